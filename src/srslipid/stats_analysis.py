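"""Downstream statistics on droplet tables.

Covers the analyses run per embryo or per group: binning droplet aggregates
into 5 μm³ size intervals and regressing mean unsaturation on size (with a
95% confidence band), frequency distributions of per-droplet unsaturation,
and normality-gated two-group comparison (Shapiro–Wilk at α = 0.05 deciding
between an equal-variance two-sample t-test and a two-sided Mann–Whitney U).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io_stacks import LipidDroplet

__all__ = [
    "SizeBinSummary",
    "GroupComparisonResult",
    "RegressionResult",
    "bin_by_size",
    "regress_with_ci",
    "compare_groups",
    "frequency_distribution",
]


@dataclass(frozen=True)
class SizeBinSummary:
    """Mean unsaturation of all droplet aggregates inside one size interval."""

    bin_lower: float
    bin_upper: float
    n_droplets: int
    mean_unsaturation: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of the normality-gated two-group test."""

    test_name: str  # "t-test" or "Mann-Whitney U"
    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS line with t-based confidence intervals for the mean response."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    x_grid: np.ndarray
    mean_ci_lower: np.ndarray
    mean_ci_upper: np.ndarray
    r_squared: float
    n: int


def bin_by_size(
    droplets: Sequence[LipidDroplet], bin_width: float = 5.0
) -> list[SizeBinSummary]:
    """Group measured droplets into half-open volume bins [k·w, (k+1)·w) μm³.

    Returns the per-bin unweighted mean unsaturation; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    meas = [d for d in droplets if d.measured]
    summaries: dict[int, list[float]] = {}
    for d in meas:
        k = int(np.floor(d.volume / bin_width))
        summaries.setdefault(k, []).append(d.mean_unsaturation)
    return [
        SizeBinSummary(
            bin_lower=k * bin_width,
            bin_upper=(k + 1) * bin_width,
            n_droplets=len(us),
            mean_unsaturation=float(np.mean(us)),
        )
        for k, us in sorted(summaries.items())
    ]


def regress_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    confidence: float = 0.95,
    grid_size: int = 50,
    weights: Sequence[float] | None = None,
) -> RegressionResult:
    """OLS of y on x with CIs from the t-distribution (n − 2 df).

    The band is for the mean response, evaluated on an even grid spanning
    the data.  ``weights`` switches to weighted least squares — when the
    points are bin means, weighting by bin count matches their variances
    (Var(mean) ∝ 1/n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    X = sm.add_constant(x)
    if weights is None:
        res = sm.OLS(y, X).fit()
    else:
        res = sm.WLS(y, X, weights=np.asarray(weights, dtype=float)).fit()
    alpha = 1.0 - confidence
    ci = res.conf_int(alpha=alpha)
    grid = np.linspace(x.min(), x.max(), grid_size)
    pred = res.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=alpha)
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        x_grid=grid,
        mean_ci_lower=band[:, 0],
        mean_ci_upper=band[:, 1],
        r_squared=r2,
        n=int(x.size),
    )


_EXACT_MAX_N = 8


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro–Wilk is run on each group; if both pass at ``alpha`` a two-tailed
    two-sample t-test is used (equal-variance by default, Welch optional),
    otherwise a two-sided Mann–Whitney U — with the exact null distribution
    when min(n) ≤ 8 and the samples are tie-free, and the tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    p_norm_a = float(stats.shapiro(a).pvalue)
    p_norm_b = float(stats.shapiro(b).pvalue)
    if p_norm_a > alpha and p_norm_b > alpha:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        name, statistic, p = "t-test", float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (min(a.size, b.size) <= _EXACT_MAX_N and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        name, statistic, p = "Mann-Whitney U", float(res.statistic), float(res.pvalue)
    return GroupComparisonResult(
        test_name=name,
        statistic=statistic,
        p_value=min(p, 1.0),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def frequency_distribution(
    values: Sequence[float], bin_edges: Sequence[float]
) -> list[tuple[tuple[float, float], int, float]]:
    """Histogram over half-open bins [e_k, e_{k+1}); fractions over in-range values.

    Returns (bin, count, fraction) triples; fractions sum to 1 over the
    values that fall inside the edge range (empty input gives fraction 0).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    values = np.asarray(values, dtype=float)
    counts = np.zeros(edges.size - 1, dtype=int)
    for i in range(edges.size - 1):
        counts[i] = int(np.count_nonzero((values >= edges[i]) & (values < edges[i + 1])))
    total = counts.sum()
    return [
        (
            (float(edges[i]), float(edges[i + 1])),
            int(counts[i]),
            float(counts[i] / total) if total else 0.0,
        )
        for i in range(edges.size - 1)
    ]
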