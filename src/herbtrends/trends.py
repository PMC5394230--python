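"""Trend and association statistics for annual series.

Provides the Mann-Kendall monotonic-trend test (tau-b, exact null for
small tie-free samples, tie-corrected normal approximation otherwise),
an ordinary-least-squares slope test against calendar year, and the
Pearson correlation.  Series use surveyed years only — gaps are allowed
and year is always the regressor.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from functools import lru_cache
from math import sqrt
from typing import Literal

from scipy import stats

from herbtrends.errors import ValidationError

StatisticKind = Literal["mann_kendall_tau", "ols_slope", "pearson_r"]

#: Largest n for which the exact Mann-Kendall null distribution is used.
EXACT_MK_LIMIT = 10


@dataclass(frozen=True)
class TrendResult:
    statistic_kind: StatisticKind
    estimate: float
    p_value: float
    n: int
    method_note: str

    def __post_init__(self) -> None:
        if self.statistic_kind in ("mann_kendall_tau", "pearson_r") and not -1.0 - 1e-12 <= self.estimate <= 1.0 + 1e-12:
            raise ValidationError(f"{self.statistic_kind} estimate outside [-1, 1]: {self.estimate}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


def _check_series(series: Sequence[tuple[int, float]]) -> tuple[list[int], list[float]]:
    if len(series) < 3:
        raise ValidationError(f"need at least 3 points, got {len(series)}")
    ordered = sorted(series)
    years = [y for y, _ in ordered]
    if len(set(years)) != len(years):
        raise ValidationError("years must be distinct")
    return years, [v for _, v in ordered]


@lru_cache(maxsize=32)
def _inversion_counts(n: int) -> tuple[int, ...]:
    """counts[d] = number of permutations of n items with d inversions."""
    counts = [1]
    for m in range(2, n + 1):
        new = [0] * (len(counts) + m - 1)
        for d, c in enumerate(counts):
            for j in range(m):
                new[d + j] += c
        counts = new
    return tuple(counts)


def exact_mk_p(s: int, n: int) -> float:
    """Two-sided exact P(|S| >= |s|) under the tie-free Mann-Kendall null.

    Uses the inversion-count distribution: for distinct values,
    S = n(n-1)/2 - 2 * (number of discordant pairs).
    """
    counts = _inversion_counts(n)
    n0 = n * (n - 1) // 2
    s = abs(s)
    if s == 0:
        return 1.0
    # S >= s  <=>  d <= (n0 - s) / 2 ; S and n0 share parity
    dmax = (n0 - s) // 2
    tail = sum(counts[: dmax + 1])
    total = sum(counts)
    return min(1.0, 2.0 * tail / total)


def mann_kendall(series: Sequence[tuple[int, float]]) -> TrendResult:
    """Mann-Kendall test for monotonic trend on an annual series.

    tau is Kendall's tau-b (tie-corrected denominator).  The two-sided p
    is exact (enumeration of the S null distribution) for tie-free
    series with n <= 10, otherwise a normal approximation with
    tie-corrected variance and continuity correction.
    """
    years, values = _check_series(series)
    n = len(values)
    n0 = n * (n - 1) // 2

    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = values[j] - values[i]
            s += (diff > 0) - (diff < 0)

    tie_sizes = [values.count(v) for v in set(values)]
    t_v = sum(t * (t - 1) // 2 for t in tie_sizes)
    if n0 - t_v == 0:  # all values identical
        return TrendResult("mann_kendall_tau", 0.0, 1.0, n, "degenerate: constant series")
    tau = s / sqrt(n0 * (n0 - t_v))

    has_ties = any(t > 1 for t in tie_sizes)
    if n <= EXACT_MK_LIMIT and not has_ties:
        return TrendResult("mann_kendall_tau", tau, exact_mk_p(s, n), n, "exact")

    var_s = (n * (n - 1) * (2 * n + 5) - sum(t * (t - 1) * (2 * t + 5) for t in tie_sizes)) / 18.0
    if s > 0:
        z = (s - 1) / sqrt(var_s)
    elif s < 0:
        z = (s + 1) / sqrt(var_s)
    else:
        z = 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TrendResult("mann_kendall_tau", tau, p, n, "normal-approx")


def ols_slope(series: Sequence[tuple[int, float]]) -> TrendResult:
    """Least-squares slope of value on year with a two-sided t-test (df n-2)."""
    years, values = _check_series(series)
    n = len(values)
    if len(set(values)) == 1:
        return TrendResult("ols_slope", 0.0, 1.0, n, "degenerate: constant series")
    fit = stats.linregress(years, values)
    p = float(fit.pvalue)
    return TrendResult("ols_slope", float(fit.slope), min(1.0, max(0.0, p)), n, f"t-test, df={n - 2}")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Sample Pearson r with a two-sided t-transform p (df n-2)."""
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError(f"need at least 3 points, got {len(x)}")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValidationError("Pearson correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return TrendResult("pearson_r", float(r), float(p), len(x), f"t-transform, df={len(x) - 2}")
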