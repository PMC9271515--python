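"""Demand/supply data model: population grids, trial sites, incidence, geodesy.

The demand surface is a uniform latitude/longitude grid of population counts
(one point per cell, nominally every 0.5 degrees, ~55 km at the equator).
Supply is a table of trial sites with per-year activated-trial counts.
Expected patients at a grid point are the product of its population and the
national cancer incidence rate. All distances are great-circle (haversine)
on the WGS84 mean Earth radius; at global 30-arc-min scale a planar
projection would be badly distorted, so no projection is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Kilometres per degree of a great-circle arc.
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_coords(lat: float, lon: float, what: str = "point") -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"{what}: lat {lat!r} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValidationError(f"{what}: lon {lon!r} outside [-180, 180]")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) pairs.

    Symmetric, non-negative and zero iff the coordinates coincide.
    """
    _check_coords(a[0], a[1], "a")
    _check_coords(b[0], b[1], "b")
    return float(haversine_km_vec(a[0], a[1], np.asarray(b[0]), np.asarray(b[1])))


def haversine_km_vec(lat0: float, lon0: float, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Vectorized haversine from one point to arrays of points (km)."""
    phi0 = math.radians(lat0)
    phi1 = np.radians(lats)
    dphi = phi1 - phi0
    dlam = np.radians(lons) - math.radians(lon0)
    h = np.sin(dphi / 2.0) ** 2 + math.cos(phi0) * np.cos(phi1) * np.sin(dlam / 2.0) ** 2
    # guard fp noise: h in [0, 1]
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


@dataclass(frozen=True)
class GridPoint:
    """One cell of the population grid (p_i lives here)."""

    id: str
    lat: float
    lon: float
    population: float
    country: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", float(self.lon))
        object.__setattr__(self, "population", float(self.population))
        _check_coords(self.lat, self.lon, f"grid point {self.id}")
        if self.population < 0:
            raise ValidationError(f"grid point {self.id}: population {self.population} < 0")


@dataclass(frozen=True)
class TrialSite:
    """A trial location in a given year with n_trials activated there (n_j)."""

    id: str
    lat: float
    lon: float
    year: int
    n_trials: int
    country: str
    funder: str | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        _check_coords(self.lat, self.lon, f"site {self.id}")
        if self.n_trials < 1:
            raise ValidationError(f"site {self.id}: n_trials {self.n_trials} < 1")


@dataclass(frozen=True)
class NearestAssignment:
    """Nearest-supply assignment of one grid point (d_ij before flooring)."""

    point_id: str
    site_id: str
    distance_km: float


class PopulationGrid:
    """An ordered collection of grid points with a nominal spacing.

    Ids must be unique and no two points may share coordinates.
    """

    def __init__(self, points: Sequence[GridPoint], spacing_deg: float = 0.5):
        points = list(points)
        if not points:
            raise ValidationError("PopulationGrid requires at least one point")
        ids = [p.id for p in points]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate grid point ids")
        coords = [(p.lat, p.lon) for p in points]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate (lat, lon) pairs in grid")
        if spacing_deg <= 0:
            raise ValidationError("spacing_deg must be > 0")
        self.points = points
        self.spacing_deg = float(spacing_deg)
        self._by_id = {p.id: p for p in points}

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, point_id: str) -> GridPoint:
        return self._by_id[point_id]

    def countries(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.points:
            seen.setdefault(p.country, None)
        return list(seen)

    def for_country(self, country: str) -> "PopulationGrid":
        pts = [p for p in self.points if p.country == country]
        if not pts:
            raise ValidationError(f"no grid points for country {country!r}")
        return PopulationGrid(pts, self.spacing_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.points],
                "lat": [p.lat for p in self.points],
                "lon": [p.lon for p in self.points],
                "population": [p.population for p in self.points],
                "country": [p.country for p in self.points],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spacing_deg: float = 0.5) -> "PopulationGrid":
        required = {"id", "lat", "lon", "population", "country"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"grid table missing columns: {sorted(missing)}")
        points = [
            GridPoint(str(r.id), float(r.lat), float(r.lon), float(r.population), str(r.country))
            for r in df.itertuples(index=False)
        ]
        return cls(points, spacing_deg)

    @classmethod
    def read_csv(cls, path: str | Path, spacing_deg: float = 0.5) -> "PopulationGrid":
        return cls.from_frame(pd.read_csv(path, dtype={"id": str, "country": str}), spacing_deg)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class SiteTable:
    """The supply side: trial sites with per-year counts and optional strata."""

    def __init__(self, sites: Iterable[TrialSite]):
        self.sites = list(sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def for_year(self, year: int, cumulative: bool = False) -> "SiteTable":
        """Sites contributing to a given year.

        Default: sites registered in that year. ``cumulative=True`` pools all
        registrations up to and including the year, summing counts per
        location id.
        """
        if not cumulative:
            return SiteTable([s for s in self.sites if s.year == year])
        pooled: dict[str, TrialSite] = {}
        for s in sorted(self.sites, key=lambda s: (s.id, s.year)):
            if s.year > year:
                continue
            if s.id in pooled:
                prev = pooled[s.id]
                pooled[s.id] = TrialSite(
                    s.id, s.lat, s.lon, year, prev.n_trials + s.n_trials,
                    s.country, s.funder, s.phase,
                )
            else:
                pooled[s.id] = TrialSite(s.id, s.lat, s.lon, year, s.n_trials, s.country, s.funder, s.phase)
        return SiteTable(pooled.values())

    def for_country(self, country: str) -> "SiteTable":
        return SiteTable([s for s in self.sites if s.country == country])

    def filter_strata(self, funder: str | None = None, phase: str | None = None) -> "SiteTable":
        out = self.sites
        if funder is not None:
            out = [s for s in out if s.funder == funder]
        if phase is not None:
            out = [s for s in out if s.phase == phase]
        return SiteTable(out)

    def years(self) -> list[int]:
        return sorted({s.year for s in self.sites})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.sites],
                "lat": [s.lat for s in self.sites],
                "lon": [s.lon for s in self.sites],
                "year": [s.year for s in self.sites],
                "n_trials": [s.n_trials for s in self.sites],
                "country": [s.country for s in self.sites],
                "funder": [s.funder for s in self.sites],
                "phase": [s.phase for s in self.sites],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteTable":
        required = {"id", "lat", "lon", "year", "n_trials", "country"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"site table missing columns: {sorted(missing)}")
        sites = []
        for r in df.itertuples(index=False):
            funder = getattr(r, "funder", None)
            phase = getattr(r, "phase", None)
            funder = None if funder is None or (isinstance(funder, float) and math.isnan(funder)) else str(funder)
            phase = None if phase is None or (isinstance(phase, float) and math.isnan(phase)) else str(phase)
            sites.append(
                TrialSite(str(r.id), float(r.lat), float(r.lon), int(r.year),
                          int(r.n_trials), str(r.country), funder, phase)
            )
        return cls(sites)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SiteTable":
        return cls.from_frame(pd.read_csv(path, dtype={"id": str, "country": str}))

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        if df["funder"].isna().all() and df["phase"].isna().all():
            df = df.drop(columns=["funder", "phase"])
        df.to_csv(path, index=False)


class IncidenceTable:
    """Country -> cancer incidence rate per 100 000 persons per year (r_c)."""

    def __init__(self, rates: Mapping[str, float]):
        for c, r in rates.items():
            if r <= 0:
                raise ValidationError(f"incidence rate for {c!r} must be > 0, got {r}")
        self.rates = dict(rates)

    def __getitem__(self, country: str) -> float:
        return self.rates[country]

    def __contains__(self, country: str) -> bool:
        return country in self.rates

    def require(self, countries: Iterable[str]) -> None:
        missing = sorted({c for c in countries if c not in self.rates})
        if missing:
            raise ValidationError(f"missing incidence rates for countries: {missing}")

    @classmethod
    def read_csv(cls, path: str | Path) -> "IncidenceTable":
        df = pd.read_csv(path, dtype={"country": str})
        required = {"country", "rate_per_100k"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"incidence table missing columns: {sorted(missing)}")
        return cls(dict(zip(df["country"], df["rate_per_100k"].astype(float))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"country": list(self.rates), "rate_per_100k": list(self.rates.values())}
        ).to_csv(path, index=False)


class NoSupplyError(LookupError):
    """No trial site exists for the demand point — accessibility is zero."""


def _site_sort_key(distance: float, site: TrialSite) -> tuple:
    # ties: closer wins; at equal distance the larger site, then lexicographic id
    return (distance, -site.n_trials, site.id)


def nearest_site(point: GridPoint, sites: Sequence[TrialSite]) -> NearestAssignment:
    """Assign a grid point to its closest trial site.

    Ties at equal distance are broken toward the site with more trials, then
    by lexicographic site id, so the assignment is deterministic.

    Raises :class:`NoSupplyError` when ``sites`` is empty, so callers can
    record zero accessibility for unserved countries.
    """
    sites = list(sites)
    if not sites:
        raise NoSupplyError("no trial sites supplied")
    lats = np.array([s.lat for s in sites])
    lons = np.array([s.lon for s in sites])
    d = haversine_km_vec(point.lat, point.lon, lats, lons)
    best = min(range(len(sites)), key=lambda i: _site_sort_key(d[i], sites[i]))
    return NearestAssignment(point.id, sites[best].id, float(d[best]))


def patients_at_point(population: float, rate: float, per_100k: bool = True) -> float:
    """Expected patients s_i = p_i * r_c (rate per 100 000 by default).

    With ``per_100k=True`` (default) the rate is divided by 100 000, so the
    result is an expected patient count. ``per_100k=False`` applies the raw
    product; within a country all relative results are invariant to this
    constant.
    """
    if population < 0:
        raise ValidationError(f"population {population} < 0")
    if rate <= 0:
        raise ValidationError(f"incidence rate {rate} must be > 0")
    scale = 1e-5 if per_100k else 1.0
    return population * rate * scale
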