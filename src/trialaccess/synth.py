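"""Synthetic countries: grids, sites, incidence and cost matrices.

Emulates the three real inputs of the pipeline — a gridded population
demand surface, geocoded per-year trial-site tables, and national incidence
rates — plus travel-cost matrices, with controlled spatial structure so
every downstream stage is testable without external data. Blueprints operate
in grid-index space: populations are per-cell counts and no latitude cell-
area correction is applied (real gridded-population cells shrink toward the
poles; these do not).

All generators are pure functions of (blueprint, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from trialaccess.access import (
    AccessSurface,
    CostMatrix,
    ImpedanceSpec,
    NationalSeries,
    compute_national_series,
    compute_surface,
)
from trialaccess.grid import (
    GridPoint,
    IncidenceTable,
    PopulationGrid,
    SiteTable,
    TrialSite,
    ValidationError,
    haversine_km_vec,
)

POPULATION_PATTERNS = ("uniform", "urban_poles", "gradient")
SITE_POLICIES = ("concentrated", "proportional", "random")
FIXTURE_NAMES = ("two_lobe", "single_pole", "uniform", "boot")


@dataclass(frozen=True)
class CountryBlueprint:
    """Recipe for one synthetic country.

    The bounding box is sampled on a uniform lat/lon lattice at
    ``spacing_deg`` (default 0.5 degrees, mirroring a 30-arc-min population
    grid). ``population_pattern`` shapes the demand surface: ``uniform``
    spreads people evenly, ``urban_poles`` concentrates ``pole_mass_share``
    of them in ``n_poles`` cells with geometrically decreasing masses (the
    poles-of-urbanization structure that drives within-country inequality),
    ``gradient`` ramps population west to east. ``site_policy`` places each
    year's trials: ``concentrated`` puts at least ``concentrated_share`` of
    them at the most populous host cell, ``proportional`` allocates them in
    proportion to host population, ``random`` scatters them. An optional
    ``mask`` (rows of '1'/'0' characters, north to south) carves
    non-rectangular territories such as a boot-shaped coastline.
    """

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    spacing_deg: float = 0.5
    population_pattern: str = "urban_poles"
    n_poles: int = 3
    pole_mass_share: float = 0.7
    pole_equal_masses: bool = False
    pole_dispersion_cells: float = 0.0
    total_population: float = 5_000_000.0
    incidence_rate: float = 300.0
    site_policy: str = "proportional"
    n_locations: int = 3
    trials_per_year_mean: float = 8.0
    concentrated_share: float = 0.85
    years: tuple[int, ...] = (2019,)
    seed: int = 0
    mask: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.lat_max < self.lat_min or self.lon_max < self.lon_min:
            raise ValidationError("degenerate bounding box")
        if self.total_population <= 0:
            raise ValidationError("total_population must be > 0")
        if self.incidence_rate <= 0:
            raise ValidationError("incidence_rate must be > 0")
        if self.population_pattern not in POPULATION_PATTERNS:
            raise ValidationError(f"unknown population pattern {self.population_pattern!r}")
        if self.site_policy not in SITE_POLICIES:
            raise ValidationError(f"unknown site policy {self.site_policy!r}")
        if not (0.0 <= self.pole_mass_share <= 1.0):
            raise ValidationError("pole_mass_share must be in [0, 1]")
        if not (0.0 < self.concentrated_share <= 1.0):
            raise ValidationError("concentrated_share must be in (0, 1]")
        object.__setattr__(self, "years", tuple(self.years))
        if self.mask is not None:
            object.__setattr__(self, "mask", tuple(self.mask))


def _lattice(bp: CountryBlueprint) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    lats = np.arange(bp.lat_max, bp.lat_min - 1e-9, -bp.spacing_deg)  # north to south
    lons = np.arange(bp.lon_min, bp.lon_max + 1e-9, bp.spacing_deg)
    cells = []
    for r in range(len(lats)):
        for c in range(len(lons)):
            if bp.mask is not None:
                if r >= len(bp.mask) or c >= len(bp.mask[r]) or bp.mask[r][c] != "1":
                    continue
            cells.append((r, c))
    if not cells:
        raise ValidationError("blueprint yields zero grid cells")
    return lats, lons, cells


def _populations(bp: CountryBlueprint, cells: list[tuple[int, int]], rng: np.random.Generator) -> np.ndarray:
    n = len(cells)
    pop = np.zeros(n)
    if bp.population_pattern == "uniform":
        pop[:] = bp.total_population / n
    elif bp.population_pattern == "gradient":
        w = np.array([c + 1.0 for _, c in cells])
        pop = bp.total_population * w / w.sum()
    else:  # urban_poles
        n_poles = min(bp.n_poles, n)
        pole_idx = rng.choice(n, size=n_poles, replace=False)
        geom = np.ones(n_poles) if bp.pole_equal_masses else 0.5 ** np.arange(n_poles)
        pole_mass = bp.total_population * bp.pole_mass_share * geom / geom.sum()
        background = bp.total_population * (1.0 - bp.pole_mass_share)
        non_pole = [i for i in range(n) if i not in set(pole_idx.tolist())]
        if non_pole:
            pop[non_pole] = background / len(non_pole)
        elif background > 0:
            pop[:] = background / n
        if bp.pole_dispersion_cells > 0:
            # spread each pole mass over a gaussian kernel in index space
            rows = np.array([r for r, _ in cells], dtype=float)
            cols = np.array([c for _, c in cells], dtype=float)
            for i, mass in zip(pole_idx, pole_mass):
                d2 = (rows - rows[i]) ** 2 + (cols - cols[i]) ** 2
                k = np.exp(-d2 / (2.0 * bp.pole_dispersion_cells**2))
                pop += mass * k / k.sum()
        else:
            for i, mass in zip(pole_idx, pole_mass):
                pop[i] += mass
    return pop


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``, each >= 1."""
    m = len(shares)
    if total < m:
        raise ValidationError(f"cannot give {m} hosts at least one of {total} trials")
    raw = (total - m) * shares / shares.sum()
    base = np.floor(raw).astype(int)
    rem = total - m - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base + 1


def _year_sites(
    bp: CountryBlueprint,
    year: int,
    points: list[GridPoint],
    rng: np.random.Generator,
) -> list[TrialSite]:
    populated = [p for p in points if p.population > 0]
    n_hosts = min(bp.n_locations, len(populated))
    total = max(n_hosts, int(rng.poisson(bp.trials_per_year_mean)))

    if bp.site_policy == "random":
        idx = rng.choice(len(populated), size=n_hosts, replace=False)
        hosts = [populated[i] for i in sorted(idx)]
        counts = _largest_remainder(total, np.ones(n_hosts))
    else:
        hosts = sorted(populated, key=lambda p: (-p.population, p.id))[:n_hosts]
        if bp.site_policy == "concentrated":
            # the share contract binds: with few trials, fewer tail hosts open
            top = math.ceil(bp.concentrated_share * total)
            n_tail = min(n_hosts - 1, total - top)
            hosts = hosts[: 1 + n_tail]
            counts = np.concatenate(
                [[total - n_tail], np.ones(n_tail, dtype=int)]
            ).astype(int)
        else:  # proportional
            counts = _largest_remainder(total, np.array([p.population for p in hosts]))
    return [
        TrialSite(f"{bp.name}:y{year}:s{k}", h.lat, h.lon, year, int(c), bp.name)
        for k, (h, c) in enumerate(zip(hosts, counts))
    ]


def make_country(bp: CountryBlueprint) -> tuple[PopulationGrid, SiteTable, IncidenceTable]:
    """Materialize one blueprint into grid, per-year sites and incidence."""
    rng = np.random.default_rng(bp.seed)
    lats, lons, cells = _lattice(bp)
    pop = _populations(bp, cells, rng)
    points = [
        GridPoint(f"{bp.name}:r{r:02d}c{c:02d}", float(lats[r]), float(lons[c]), float(p), bp.name)
        for (r, c), p in zip(cells, pop)
    ]
    grid = PopulationGrid(points, bp.spacing_deg)
    sites: list[TrialSite] = []
    for year in bp.years:
        sites.extend(_year_sites(bp, year, points, rng))
    return grid, SiteTable(sites), IncidenceTable({bp.name: bp.incidence_rate})


def make_cost_matrix(
    grid: PopulationGrid,
    sites: SiteTable | Sequence[TrialSite],
    model: str = "distance",
    gamma: float = 0.5,
    seed: int = 0,
) -> CostMatrix:
    """Travel-cost matrix between every grid point and site.

    ``distance`` returns the haversine separations; ``distance_plus_congestion``
    inflates every trip leaving grid point i by ``1 + gamma * rank_i`` where
    rank_i in (0, 1] is the percentile of the point's own population (denser
    origins face more congested roads). The factor is per-origin, so costs
    always dominate distances while each point's ranking over sites — and
    hence its serving site — is preserved.
    """
    if model not in ("distance", "distance_plus_congestion"):
        raise ValidationError(f"unknown cost model {model!r}")
    site_list = list(sites)
    pops = np.array([p.population for p in grid.points])
    if model == "distance_plus_congestion":
        order = np.argsort(np.argsort(pops, kind="stable"), kind="stable")
        ranks = (order + 1) / len(pops)
    else:
        ranks = np.zeros(len(pops))
    costs: dict[tuple[str, str], float] = {}
    site_lats = np.array([s.lat for s in site_list])
    site_lons = np.array([s.lon for s in site_list])
    for i, p in enumerate(grid.points):
        d = haversine_km_vec(p.lat, p.lon, site_lats, site_lons)
        factor = 1.0 + gamma * ranks[i]
        for j, s in enumerate(site_list):
            costs[(p.id, s.id)] = float(d[j]) * factor
    return CostMatrix(costs)


GROWTH_REGIMES = ("flat", "linear", "accelerating", "decoupled")


@dataclass
class TrendPanel:
    """A panel of synthetic countries with known growth regimes.

    ``access`` holds the national accessibility series (computed through the
    full surface pipeline), ``trials`` the total registered trials per year.
    """

    regime: str
    grids: dict[str, PopulationGrid]
    sites: dict[str, SiteTable]
    incidence: IncidenceTable
    access: dict[str, NationalSeries]
    trials: dict[str, NationalSeries]
    spec: ImpedanceSpec


def _catchment_quality(surface: AccessSurface, spec: ImpedanceSpec, spacing_deg: float) -> dict[str, float]:
    """Per-site sum of floored-distance impedances over its weighable catchment.

    The national index is linear in each site's trial count with this
    quantity (divided by the total weight) as the coefficient.
    """
    q: dict[str, float] = {}
    f = surface.frame[surface.frame["weighable"]]
    for r in f.itertuples(index=False):
        if r.serving_site_id is None or (isinstance(r.serving_site_id, float) and math.isnan(r.serving_site_id)):
            continue
        floor = (
            spec.distance_floor_km
            if spec.distance_floor_km is not None
            else spec.default_floor_km(r.lat, spacing_deg)
        )
        q[r.serving_site_id] = q.get(r.serving_site_id, 0.0) + max(r.distance_km, floor) ** (-spec.beta)
    return q


def make_trend_panel(
    n_countries: int,
    regime: str,
    years: Sequence[int],
    seed: int = 0,
    spec: ImpedanceSpec = ImpedanceSpec(),
    blueprint: CountryBlueprint | None = None,
) -> TrendPanel:
    """Generate countries whose accessibility series follow a known regime.

    flat:
        fixed site locations; each site's yearly trial count is an i.i.d.
        1 + Poisson draw, so the index series is exchangeable across years
        (the null of the trend test holds).
    linear:
        every site's count grows by one trial per year, no noise; the index
        increases strictly.
    accelerating:
        counts grow quadratically in time.
    decoupled:
        all growth goes to the country's dominant hub — the site whose
        catchment contributes least accessibility per trial (few, far,
        already-served points). Total trials then rise faster than the
        national index in every country: the index gains only the hub
        catchment's per-trial coefficient, which is strictly the smallest.
    """
    if regime not in GROWTH_REGIMES:
        raise ValidationError(f"unknown growth regime {regime!r}; one of {GROWTH_REGIMES}")
    years = list(years)
    if len(years) < 3:
        raise ValidationError("a trend panel needs at least three years")
    master = np.random.default_rng(seed)
    bp0 = blueprint or CountryBlueprint(
        name="panel",
        lat_min=40.0, lat_max=44.0, lon_min=10.0, lon_max=14.0,
        spacing_deg=1.0,
        population_pattern="urban_poles",
        n_poles=3,
        pole_mass_share=0.7,
        total_population=8_000_000.0,
        incidence_rate=300.0,
        n_locations=3,
        # a stable mid-size country registers tens of trials a year; this also
        # keeps the index series effectively tie-free, so the nominal level of
        # the trend test is meaningful on the flat regime
        trials_per_year_mean=60.0,
        years=tuple(years),
    )

    grids: dict[str, PopulationGrid] = {}
    site_tables: dict[str, SiteTable] = {}
    rates: dict[str, float] = {}
    trials: dict[str, NationalSeries] = {}

    for ci in range(n_countries):
        name = f"{bp0.name}{ci:03d}"
        c_seed = int(master.integers(0, 2**31 - 1))
        bp = replace(bp0, name=name, seed=c_seed, years=tuple(years))
        rng = np.random.default_rng(c_seed)
        lats, lons, cells = _lattice(bp)
        pop = _populations(bp, cells, rng)
        points = [
            GridPoint(f"{name}:r{r:02d}c{c:02d}", float(lats[r]), float(lons[c]), float(p), name)
            for (r, c), p in zip(cells, pop)
        ]
        grid = PopulationGrid(points, bp.spacing_deg)
        populated = [p for p in points if p.population > 0]
        hosts = sorted(populated, key=lambda p: (-p.population, p.id))[: bp.n_locations]

        sites: list[TrialSite] = []
        if regime == "flat":
            for y in years:
                for k, h in enumerate(hosts):
                    n = 1 + int(rng.poisson(bp.trials_per_year_mean / len(hosts)))
                    sites.append(TrialSite(f"{name}:y{y}:s{k}", h.lat, h.lon, y, n, name))
        elif regime in ("linear", "accelerating"):
            base = [3 + k for k in range(len(hosts))]
            for t, y in enumerate(years):
                growth = t if regime == "linear" else t * t
                for k, h in enumerate(hosts):
                    sites.append(
                        TrialSite(f"{name}:y{y}:s{k}", h.lat, h.lon, y, base[k] + growth, name)
                    )
        else:  # decoupled
            base_year = years[0]
            probe = [
                TrialSite(f"{name}:s{k}", h.lat, h.lon, base_year, 1, name)
                for k, h in enumerate(hosts)
            ]
            surf = compute_surface(
                grid, probe, IncidenceTable({name: bp.incidence_rate}), spec, year=base_year
            )
            q = _catchment_quality(surf, spec, bp.spacing_deg)
            served = [s for s in probe if s.id in q]
            if len({round(v, 12) for v in q.values()}) < 2:
                raise ValidationError(
                    f"{name}: degenerate geometry, all catchments equal; vary the blueprint"
                )
            hub_id = min(served, key=lambda s: (q[s.id], s.id)).id
            hub_host = {s.id: h for s, h in zip(probe, hosts)}[hub_id]
            others = [h for k, h in enumerate(hosts) if probe[k].id != hub_id]
            hub_base = 4 * max(len(hosts), 2)  # hub starts as the largest site
            for t, y in enumerate(years):
                sites.append(
                    TrialSite(f"{name}:y{y}:hub", hub_host.lat, hub_host.lon, y,
                              hub_base + 3 * t, name)
                )
                for k, h in enumerate(others):
                    sites.append(TrialSite(f"{name}:y{y}:s{k}", h.lat, h.lon, y, 2, name))

        grids[name] = grid
        site_tables[name] = SiteTable(sites)
        rates[name] = bp.incidence_rate
        totals = {
            y: float(sum(s.n_trials for s in sites if s.year == y)) for y in years
        }
        trials[name] = NationalSeries(name, totals)

    incidence = IncidenceTable(rates)
    access: dict[str, NationalSeries] = {}
    for name, grid in grids.items():
        series = compute_national_series(grid, site_tables[name], incidence, spec, years=years)
        access[name] = series[name]
    return TrendPanel(regime, grids, site_tables, incidence, access, trials, spec)


def load_fixture(name: str) -> CountryBlueprint:
    """Load one of the named toy-country blueprints shipped with the package."""
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; one of {FIXTURE_NAMES}")
    text = resources.files("trialaccess").joinpath(f"fixtures/{name}.yaml").read_text()
    data = yaml.safe_load(text)
    if "years" in data:
        data["years"] = tuple(data["years"])
    if "mask" in data and data["mask"] is not None:
        data["mask"] = tuple(data["mask"])
    return CountryBlueprint(**data)


def blueprint_from_yaml(path: str) -> CountryBlueprint:
    """Read a blueprint from a YAML file (same schema as the fixtures)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "years" in data:
        data["years"] = tuple(data["years"])
    if "mask" in data and data["mask"] is not None:
        data["mask"] = tuple(data["mask"])
    return CountryBlueprint(**data)
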