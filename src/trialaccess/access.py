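"""Local and national accessibility indices (dAI, tAI) and normalization.

The local distance-based accessibility index at grid point *i* served by its
nearest site *j* is

    dAI(i) = n_j / log(s_i) * (1 / d_ij)**beta

with n_j the trials activated at the nearest site, s_i the expected patient
count at the point, d_ij the great-circle distance and beta = 0.5 by default
(inverse square-root decay, the exponent that best describes human mobility
at the typical patient-to-site scale). The log attenuates the very
heterogeneous patient volumes; distances are floored so a point co-located
with a site keeps a finite value. The national index is the average of the
local values weighted by log(s_i).

The travel-cost variant (tAI) is the identical formula with a generalized
travel cost replacing great-circle distance, the serving site being the
cost-minimizing one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trialaccess.grid import (
    KM_PER_DEG,
    IncidenceTable,
    NoSupplyError,
    PopulationGrid,
    SiteTable,
    TrialSite,
    ValidationError,
    haversine_km_vec,
    patients_at_point,
)

#: Weights below this are clamped; points with s_i <= 1 are excluded entirely.
WEIGHT_CLAMP = 1.0


class ConfigurationError(ValueError):
    """Invalid impedance or aggregation configuration."""


class NoWeighablePopulation(ValueError):
    """Every grid point of the surface was excluded from aggregation."""


@dataclass(frozen=True)
class ImpedanceSpec:
    """Impedance configuration for the accessibility formula.

    Parameters
    ----------
    beta:
        Distance-decay exponent (> 0). Default 0.5 (inverse square root).
    distance_floor_km:
        Lower bound applied to distance (or cost) before the power law.
        ``None`` (default) floors each point at half its grid-cell diagonal,
        which depends on latitude; a scalar applies one floor everywhere.
        Standalone ``local_dai`` calls without a resolvable floor use 1 km.
    cost_mode:
        "distance" for dAI, "travel_cost" for tAI.
    log_base:
        Base of the patient-volume logarithm; natural log by default. All
        within-country relative comparisons are invariant to the base.
    per_100k:
        Divide incidence by 100 000 so s_i is an expected patient count.
    """

    beta: float = 0.5
    distance_floor_km: float | None = None
    cost_mode: str = "distance"
    log_base: float = math.e
    per_100k: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")
        if self.distance_floor_km is not None and self.distance_floor_km <= 0:
            raise ConfigurationError(f"distance floor must be > 0, got {self.distance_floor_km}")
        if self.cost_mode not in ("distance", "travel_cost"):
            raise ConfigurationError(f"unknown cost_mode {self.cost_mode!r}")
        if self.log_base <= 1:
            raise ConfigurationError("log_base must be > 1")

    def default_floor_km(self, lat: float, spacing_deg: float) -> float:
        """Half the grid-cell diagonal at a given latitude, in km."""
        a = spacing_deg * KM_PER_DEG                     # N-S cell side
        b = a * abs(math.cos(math.radians(lat)))          # E-W side shrinks with latitude
        return math.sqrt(a * a + b * b) / 2.0

    def log(self, x: float | np.ndarray):
        if self.log_base == math.e:
            return np.log(x)
        return np.log(x) / math.log(self.log_base)


def local_dai(
    n_trials: float,
    distance_km: float,
    patients: float,
    spec: ImpedanceSpec = ImpedanceSpec(),
    floor_km: float | None = None,
) -> float:
    """Local accessibility value for one grid point / nearest-site pair.

    ``n_trials / max(log(patients), 1) * (1 / max(distance, floor))**beta``.
    The log clamp keeps the value finite and positive for small patient
    volumes; exclusion of points with at most one expected patient from
    national aggregation happens downstream.
    """
    if n_trials < 1:
        raise ValidationError(f"n_trials {n_trials} < 1")
    if distance_km < 0:
        raise ValidationError(f"distance {distance_km} < 0")
    if patients < 0:
        raise ValidationError(f"patients {patients} < 0")
    floor = floor_km if floor_km is not None else spec.distance_floor_km
    if floor is None:
        floor = 1.0
    if floor <= 0:
        raise ConfigurationError(f"distance floor must be > 0, got {floor}")
    w = max(float(spec.log(patients)) if patients > 0 else 0.0, WEIGHT_CLAMP)
    d = max(distance_km, floor)
    return n_trials / w * d ** (-spec.beta)


class AccessSurface:
    """Per-grid-point local accessibility values with aggregation weights.

    Backed by a DataFrame with one row per populated grid point:
    ``point_id, lat, lon, country, population, patients, local_value,
    weight, weighable, serving_site_id, distance_km``. ``weighable`` is False
    for points with at most one expected patient; those are kept in the
    surface (their local value is still a valid map datum) but excluded from
    the national weighted average.
    """

    COLUMNS = [
        "point_id", "lat", "lon", "country", "population", "patients",
        "local_value", "weight", "weighable", "serving_site_id", "distance_km",
    ]

    def __init__(self, frame: pd.DataFrame, year: int | None = None):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"surface missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValidationError("empty access surface")
        if (frame["local_value"] < 0).any():
            raise ValidationError("negative local accessibility value")
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]
        self.year = year

    def __len__(self) -> int:
        return len(self.frame)

    def local_values(self) -> np.ndarray:
        return self.frame["local_value"].to_numpy(dtype=float)

    def countries(self) -> list[str]:
        return list(dict.fromkeys(self.frame["country"]))

    def for_country(self, country: str) -> "AccessSurface":
        sub = self.frame[self.frame["country"] == country]
        if len(sub) == 0:
            raise ValidationError(f"no surface points for {country!r}")
        return AccessSurface(sub, self.year)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, year: int | None = None) -> "AccessSurface":
        return cls(pd.read_csv(path, dtype={"point_id": str, "country": str}), year)

    def to_geojson(self, path: str | Path) -> None:
        """Write a GeoJSON FeatureCollection of Point features for mapping."""
        features = []
        for r in self.frame.itertuples(index=False):
            props = {
                "point_id": r.point_id,
                "country": r.country,
                "population": r.population,
                "local_value": r.local_value,
                "weight": r.weight,
                "weighable": bool(r.weighable),
                "serving_site_id": None if pd.isna(r.serving_site_id) else r.serving_site_id,
                "distance_km": None if pd.isna(r.distance_km) else r.distance_km,
            }
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class NationalSeries:
    """Country-level index values per year, the unit of all trend statistics."""

    country: str
    values: dict[int, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValidationError("national index values must be >= 0")
        self.values = dict(sorted(self.values.items()))

    def years(self) -> list[int]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def mean_over(self, years: Iterable[int]) -> float:
        vals = [self.values[y] for y in years if y in self.values]
        if not vals:
            raise ValidationError(f"{self.country}: no values in requested years")
        return float(np.mean(vals))


class CostMatrix:
    """Generalized travel cost for (point, site) pairs; must be complete.

    Zero cost is allowed for a co-located pair (the impedance floor handles
    it downstream, exactly as it does for zero distance).
    """

    def __init__(self, costs: Mapping[tuple[str, str], float]):
        for (p, s), c in costs.items():
            if c < 0:
                raise ValidationError(f"cost for ({p}, {s}) must be >= 0, got {c}")
        self.costs = dict(costs)

    def __getitem__(self, key: tuple[str, str]) -> float:
        try:
            return self.costs[key]
        except KeyError:
            raise ValidationError(f"missing cost for point {key[0]!r}, site {key[1]!r}") from None

    def lookup(self, point_ids: Sequence[str], site_ids: Sequence[str]) -> np.ndarray:
        out = np.empty((len(point_ids), len(site_ids)))
        for i, p in enumerate(point_ids):
            for j, s in enumerate(site_ids):
                out[i, j] = self[(p, s)]
        return out

    @classmethod
    def read_csv(cls, path: str | Path) -> "CostMatrix":
        df = pd.read_csv(path, dtype={"point_id": str, "site_id": str})
        required = {"point_id", "site_id", "cost"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"cost matrix missing columns: {sorted(missing)}")
        return cls({(r.point_id, r.site_id): float(r.cost) for r in df.itertuples(index=False)})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(p, s, c) for (p, s), c in self.costs.items()],
            columns=["point_id", "site_id", "cost"],
        ).to_csv(path, index=False)


def _sorted_sites(sites: Iterable[TrialSite]) -> list[TrialSite]:
    # pre-sorting by (-n_trials, id) makes "first minimum" implement the
    # tie-break: closest, then larger site, then lexicographic id
    return sorted(sites, key=lambda s: (-s.n_trials, s.id))


def _impedance_surface(
    grid: PopulationGrid,
    sites: Sequence[TrialSite],
    incidence: IncidenceTable,
    spec: ImpedanceSpec,
    year: int | None,
    costs: CostMatrix | None,
) -> AccessSurface:
    populated = [p for p in grid.points if p.population > 0]
    if not populated:
        raise ValidationError("grid has no populated points")
    incidence.require({p.country for p in populated})

    site_list = _sorted_sites(sites)
    n_pts = len(populated)
    patients = np.array(
        [patients_at_point(p.population, incidence[p.country], spec.per_100k) for p in populated]
    )
    logp = np.where(patients > 0, spec.log(np.where(patients > 0, patients, 1.0)), 0.0)
    weights = np.maximum(logp, WEIGHT_CLAMP)
    weighable = patients > 1.0

    if spec.distance_floor_km is not None:
        floors = np.full(n_pts, spec.distance_floor_km)
    else:
        floors = np.array([spec.default_floor_km(p.lat, grid.spacing_deg) for p in populated])

    if not site_list:
        local = np.zeros(n_pts)
        serving = [None] * n_pts
        dist = np.full(n_pts, np.nan)
    else:
        if costs is None:
            lats = np.array([s.lat for s in site_list])
            lons = np.array([s.lon for s in site_list])
            sep = np.vstack(
                [haversine_km_vec(p.lat, p.lon, lats, lons) for p in populated]
            )
        else:
            sep = costs.lookup([p.id for p in populated], [s.id for s in site_list])
        best = np.argmin(sep, axis=1)  # first min = tie-break via pre-sort
        dist = sep[np.arange(n_pts), best]
        n_at_best = np.array([site_list[j].n_trials for j in best], dtype=float)
        serving = [site_list[j].id for j in best]
        local = n_at_best / weights * np.maximum(dist, floors) ** (-spec.beta)

    frame = pd.DataFrame(
        {
            "point_id": [p.id for p in populated],
            "lat": [p.lat for p in populated],
            "lon": [p.lon for p in populated],
            "country": [p.country for p in populated],
            "population": [p.population for p in populated],
            "patients": patients,
            "local_value": local,
            "weight": weights,
            "weighable": weighable,
            "serving_site_id": serving,
            "distance_km": dist,
        }
    )
    return AccessSurface(frame, year)


def compute_surface(
    grid: PopulationGrid,
    sites: SiteTable | Sequence[TrialSite],
    incidence: IncidenceTable,
    spec: ImpedanceSpec = ImpedanceSpec(),
    year: int | None = None,
    country: str | None = None,
    within_country: bool = False,
    cumulative: bool = False,
) -> AccessSurface:
    """Compute the dAI surface: one record per populated grid point.

    ``year`` filters sites to those registered that year (or pooled up to it
    with ``cumulative=True``); ``country`` restricts the demand grid;
    ``within_country=True`` also restricts each point's candidate sites to
    its own country (by default the nearest site may be across a border).
    """
    table = sites if isinstance(sites, SiteTable) else SiteTable(sites)
    if year is not None:
        table = table.for_year(year, cumulative=cumulative)
    if country is not None:
        grid = grid.for_country(country)
    if within_country:
        frames = []
        for c in grid.countries():
            sub = _impedance_surface(
                grid.for_country(c), list(table.for_country(c)), incidence, spec, year, None
            )
            frames.append(sub.frame)
        return AccessSurface(pd.concat(frames, ignore_index=True), year)
    return _impedance_surface(grid, list(table), incidence, spec, year, None)


def compute_tai(
    grid: PopulationGrid,
    sites: SiteTable | Sequence[TrialSite],
    incidence: IncidenceTable,
    costs: CostMatrix,
    spec: ImpedanceSpec = ImpedanceSpec(),
    year: int | None = None,
    country: str | None = None,
) -> AccessSurface:
    """Travel-cost accessibility surface (tAI).

    Identical formula with generalized cost replacing distance; each point is
    served by its cost-minimizing site (same tie-break). The cost matrix must
    contain every (point, site) pair evaluated.
    """
    table = sites if isinstance(sites, SiteTable) else SiteTable(sites)
    if year is not None:
        table = table.for_year(year)
    if country is not None:
        grid = grid.for_country(country)
    return _impedance_surface(grid, list(table), incidence, spec, year, costs)


def national_index(surface: AccessSurface) -> float:
    """Log-patient-weighted average of local accessibility values.

    Points with at most one expected patient carry no weight and are
    excluded; if every point is excluded the average is undefined and
    :class:`NoWeighablePopulation` is raised. An all-zero surface (no
    supply) aggregates to 0.
    """
    sub = surface.frame[surface.frame["weighable"]]
    if len(sub) == 0:
        raise NoWeighablePopulation(
            "no grid point has more than one expected patient; national index undefined"
        )
    w = sub["weight"].to_numpy(dtype=float)
    v = sub["local_value"].to_numpy(dtype=float)
    return float(np.sum(v * w) / np.sum(w))


def compute_national_series(
    grid: PopulationGrid,
    sites: SiteTable,
    incidence: IncidenceTable,
    spec: ImpedanceSpec = ImpedanceSpec(),
    years: Sequence[int] | None = None,
    within_country: bool = False,
    cumulative: bool = False,
) -> dict[str, NationalSeries]:
    """National index per country per year.

    Countries/years with no sites get index 0 ("no accessibility"), not a
    missing value.
    """
    if years is None:
        years = sites.years()
    out: dict[str, dict[int, float]] = {c: {} for c in grid.countries()}
    for y in years:
        surf = compute_surface(
            grid, sites, incidence, spec, year=y, within_country=within_country,
            cumulative=cumulative,
        )
        for c in grid.countries():
            try:
                out[c][y] = national_index(surf.for_country(c))
            except NoWeighablePopulation:
                out[c][y] = 0.0
    return {c: NationalSeries(c, vals) for c, vals in out.items()}


def normalize_to_reference(
    series: Iterable[NationalSeries],
    reference_country: str,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Express each country's index as a percentage of a reference country.

    Per-year ratios by default; with ``window=(start, end)`` the ratio of
    period means over the closed year interval (the convention used for
    multi-year cross-country comparisons). Years where the reference value is
    zero are kept with ``pct_of_reference`` NaN and ``defined`` False rather
    than silently dropped.
    """
    series = list(series)
    ref = next((s for s in series if s.country == reference_country), None)
    if ref is None:
        raise ValidationError(f"reference country {reference_country!r} not in series")

    if window is not None:
        y0, y1 = window
        yrs = [y for y in ref.years() if y0 <= y <= y1]
        if not yrs:
            raise ValidationError("reference has no values in the window")
        ref_mean = ref.mean_over(yrs)
        rows = []
        for s in series:
            c_yrs = [y for y in s.years() if y0 <= y <= y1]
            val = s.mean_over(c_yrs) if c_yrs else math.nan
            defined = ref_mean > 0 and not math.isnan(val)
            rows.append(
                {
                    "country": s.country,
                    "window": f"{y0}-{y1}",
                    "pct_of_reference": val / ref_mean * 100.0 if defined else math.nan,
                    "defined": defined,
                }
            )
        return pd.DataFrame(rows)

    rows = []
    for s in series:
        for y, v in s.values.items():
            rv = ref.values.get(y)
            defined = rv is not None and rv > 0
            rows.append(
                {
                    "country": s.country,
                    "year": y,
                    "pct_of_reference": v / rv * 100.0 if defined else math.nan,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)
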