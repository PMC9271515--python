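"""Time-trend analytics on national accessibility series.

Covers relative increments over a base year, trapezoidal AUC of the
increment curve (the trials-AUC vs accessibility-AUC comparison quantifies
how much trial growth decouples from accessibility growth), the
Mann-Kendall monotone-trend test with Kendall's tau-b, Pearson correlation
of increment series, and mean/SD comparison between two periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from trialaccess.access import NationalSeries
from trialaccess.grid import ValidationError


@dataclass
class IncrementSeries:
    """Percent increments of a national series over a base year."""

    country: str
    base_year: int
    increments: dict[int, float]

    def years(self) -> list[int]:
        return list(self.increments)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.increments.values()), dtype=float)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test outcome for one series."""

    country: str | None
    S: int
    tau: float
    p_value: float
    n: int
    method: str  # "exact" or "normal"

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


@dataclass(frozen=True)
class PeriodComparison:
    """Mean/SD of a series in two year periods and their difference."""

    country: str | None
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    delta: float
    flagged: bool  # True when either period mean is 0 (display convention)


def relative_increments(series: NationalSeries, base_year: int) -> IncrementSeries:
    """100 * (x_t - x_base) / x_base for every year of the series."""
    if base_year not in series.values:
        raise ValidationError(f"{series.country}: base year {base_year} not in series")
    base = series.values[base_year]
    if base <= 0:
        raise ValidationError(
            f"{series.country}: base-year value is 0; increments over it are undefined"
        )
    return IncrementSeries(
        series.country,
        base_year,
        {y: 100.0 * (v - base) / base for y, v in series.values.items()},
    )


def auc_increments(inc: IncrementSeries) -> float:
    """Trapezoidal area under percent-increment vs year index (unit spacing).

    Only AUC ratios are interpreted downstream, and those are invariant to
    the abscissa scale.
    """
    y = inc.as_array()
    if y.size < 2:
        raise ValidationError("AUC needs at least two years")
    return float(np.trapezoid(y, dx=1.0))


def decoupling_ratio(access_inc: IncrementSeries, trials_inc: IncrementSeries) -> float:
    """accessibility-AUC / trials-AUC: < 1 means access grows slower than trials."""
    return auc_increments(access_inc) / auc_increments(trials_inc)


@lru_cache(maxsize=32)
def _mahonian_counts(n: int) -> tuple[int, ...]:
    """Number of permutations of n items with k inversions, k = 0..n(n-1)/2."""
    counts = [1]
    for m in range(2, n + 1):
        prev = counts
        size = len(prev) + (m - 1)
        nxt = [0] * size
        run = 0
        # convolution with the all-ones kernel of length m, via running sum
        for k in range(size):
            if k < len(prev):
                run += prev[k]
            if k - m >= 0:
                run -= prev[k - m]
            nxt[k] = run
        counts = nxt
    return tuple(counts)


def _exact_p(n: int, s: int) -> float:
    """Two-sided P(|S| >= |s|) under the exact tie-free permutation null."""
    counts = _mahonian_counts(n)
    n0 = n * (n - 1) // 2
    # S = n0 - 2k for k inversions; the null is symmetric about 0
    total = sum(counts)
    hit = sum(c for k, c in enumerate(counts) if abs(n0 - 2 * k) >= abs(s))
    return hit / total


def mann_kendall(values: Sequence[float], country: str | None = None,
                 exact_max_n: int = 10) -> TrendResult:
    """Mann-Kendall monotone-trend test on an ordered series.

    S is the sign-sum statistic over all ordered pairs; tau is Kendall's
    tau-b (tie-corrected; the time axis has no ties). For tie-free series of
    length <= ``exact_max_n`` the p-value comes from the exact permutation
    null; otherwise from the normal approximation with tie-corrected
    variance and a +/-1 continuity correction, two-sided.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"Mann-Kendall needs n >= 3, got {n}")

    diff_sign = np.sign(x[None, :] - x[:, None])
    S = int(np.sum(np.triu(diff_sign, k=1)))

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    n0 = n * (n - 1) // 2
    n2 = int(np.sum(ties * (ties - 1) // 2))
    denom = math.sqrt(n0 * (n0 - n2))
    tau = S / denom if denom > 0 else 0.0

    has_ties = len(ties) > 0
    if not has_ties and n <= exact_max_n:
        p = _exact_p(n, S)
        method = "exact"
    else:
        var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
        if var <= 0:  # all values identical
            p, method = 1.0, "normal"
        else:
            z = (S - np.sign(S)) / math.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
            p = min(p, 1.0)
            method = "normal"
    return TrendResult(country, S, float(tau), float(p), n, method)


def pearson_corr(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("series must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("Pearson correlation undefined for zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def period_comparison(
    series: NationalSeries,
    period1: tuple[int, int],
    period2: tuple[int, int],
) -> PeriodComparison:
    """Compare the series mean between two closed year intervals.

    SDs are sample SDs (0 for a single-year period). A comparison where
    either period mean is exactly 0 is flagged — the display convention keeps
    only countries with both means nonzero — but never dropped silently.
    """
    def pick(period: tuple[int, int]) -> np.ndarray:
        y0, y1 = period
        vals = np.array([v for y, v in series.values.items() if y0 <= y <= y1])
        if vals.size == 0:
            raise ValidationError(f"{series.country}: no values in period {y0}-{y1}")
        return vals

    v1, v2 = pick(period1), pick(period2)
    sd1 = float(np.std(v1, ddof=1)) if v1.size > 1 else 0.0
    sd2 = float(np.std(v2, ddof=1)) if v2.size > 1 else 0.0
    m1, m2 = float(v1.mean()), float(v2.mean())
    return PeriodComparison(
        series.country, m1, sd1, m2, sd2, m2 - m1, flagged=(m1 == 0.0 or m2 == 0.0)
    )
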