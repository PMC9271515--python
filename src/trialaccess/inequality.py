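"""Gini-index inequality of accessibility, global and within countries.

The Gini index of a non-negative vector is the mean absolute pairwise
difference divided by twice the mean: G = sum_ij |x_i - x_j| / (2 n^2 xbar).
Zero-valued grid points (unserved areas) are included — they are precisely
the inequality being measured. A vector with zero mean (a country-year with
no trials anywhere) has no defined Gini; that is reported as an explicit
undefined marker, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trialaccess.access import AccessSurface
from trialaccess.grid import ValidationError


@dataclass(frozen=True)
class GiniResult:
    """Gini index for one scope (global or one country) in one year.

    ``gini`` is None when undefined (all values zero).
    """

    scope: str
    year: int | None
    gini: float | None
    n_units: int


def gini(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> float | None:
    """Gini index of a non-negative vector, optionally unit-weighted.

    Computed in O(n log n) from the sorted vector:

        G = sum_i (2 W_i - w_i - W) * w_i * x_i / (W * sum_i w_i * x_i)

    with W_i the cumulative weight up to unit i (values sorted ascending),
    which equals the pairwise definition
    ``sum_ij w_i w_j |x_i - x_j| / (2 W^2 xbar_w)``. Returns None (undefined)
    when the weighted mean is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("gini requires a non-empty 1-d vector")
    if (x < 0).any():
        raise ValidationError("gini values must be non-negative")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValidationError("weights length must match values length")
        if (w <= 0).any():
            raise ValidationError("weights must be positive")

    total = float(np.sum(w * x))
    if total == 0.0:
        return None

    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    W = cw[-1]
    # sum_ij w_i w_j |x_i - x_j| = 2 * sum_i w_i x_i (2 W_i - w_i - W)
    numer = 2.0 * float(np.sum(ws * xs * (2.0 * cw - ws - W)))
    return numer / (2.0 * W * total)


def gini_pairwise(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> float | None:
    """O(n^2) pairwise-definition Gini; the brute-force oracle for tests."""
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    total = float(np.sum(w * x))
    if total == 0.0:
        return None
    W = float(np.sum(w))
    diff = np.abs(x[:, None] - x[None, :])
    numer = float(np.sum(w[:, None] * w[None, :] * diff))
    return numer / (2.0 * W * total)


def within_country_gini(
    surface: AccessSurface,
    year: int | None = None,
    population_weighted: bool = False,
    min_one_trial: bool = True,
) -> list[GiniResult]:
    """Per-country Gini of local accessibility over the country's grid points.

    With ``min_one_trial`` (default) countries whose every local value is
    zero — no trial anywhere that year — are excluded, matching the
    convention of displaying only countries with at least one trial;
    their Gini would be undefined anyway.
    """
    year = year if year is not None else surface.year
    out = []
    for c in surface.countries():
        sub = surface.for_country(c)
        vals = sub.local_values()
        weights = sub.frame["population"].to_numpy(dtype=float) if population_weighted else None
        g = gini(vals, weights)
        if g is None and min_one_trial:
            continue
        out.append(GiniResult(scope=c, year=year, gini=g, n_units=len(vals)))
    return out


def global_gini(
    surface: AccessSurface,
    year: int | None = None,
    population_weighted: bool = False,
    by_national_index: Mapping[str, float] | None = None,
) -> GiniResult:
    """Gini over all grid points of all countries pooled into one vector.

    Passing ``by_national_index`` (country -> national index) switches to the
    alternative reading where the units are countries, not grid points.
    """
    year = year if year is not None else surface.year
    if by_national_index is not None:
        vals = np.array(list(by_national_index.values()), dtype=float)
        return GiniResult("global", year, gini(vals), len(vals))
    vals = surface.local_values()
    weights = surface.frame["population"].to_numpy(dtype=float) if population_weighted else None
    return GiniResult("global", year, gini(vals, weights), len(vals))


def lorenz_points(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Lorenz curve: (cumulative share of units, cumulative share of access).

    Returns an (n+1, 2) array from (0, 0) to (1, 1) over the ascending-sorted
    vector. The Gini index equals 1 - 2 * (trapezoidal area under the curve)
    up to the 1/n discretization term.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValidationError("lorenz_points requires a non-empty vector")
    if (x < 0).any():
        raise ValidationError("lorenz_points values must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValidationError("lorenz curve undefined for an all-zero vector")
    cum_units = np.arange(x.size + 1) / x.size
    cum_access = np.concatenate([[0.0], np.cumsum(x)]) / total
    return np.column_stack([cum_units, cum_access])


def gini_table(results: Iterable[GiniResult]) -> pd.DataFrame:
    """Tabulate GiniResults as `scope,year,gini,n_units` (NaN when undefined)."""
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "year": r.year,
                "gini": math.nan if r.gini is None else r.gini,
                "n_units": r.n_units,
            }
            for r in results
        ]
    )
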