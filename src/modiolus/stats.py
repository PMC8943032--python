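"""Statistical comparison layer for the morphometric populations.

Two-sample location/distribution tests (Wilcoxon–Mann–Whitney rank sum,
two-sample Kolmogorov–Smirnov), Pearson correlation with shared variance
reported as r^2 in percent, and the classic pooled-variance two-sample t
computed from summary statistics alone (for comparisons against
literature values available only as mean +/- SD).  All tests are
two-tailed; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_distributions",
    "correlate",
    "t_from_summary",
]

EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-tailed test."""

    test: str  # rank_sum | ks | pearson | t_from_summary
    statistic: float
    p_value: float
    n1: int
    n2: int
    effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def _clean(sample) -> np.ndarray:
    v = np.asarray(list(sample), float)
    return v[~np.isnan(v)]


def compare_distributions(a, b, test: str = "rank_sum") -> ComparisonResult:
    """Two-tailed rank-sum or Kolmogorov–Smirnov comparison of two samples.

    The rank sum uses exact enumeration for small samples (both n <= 20
    and no ties) and the tie-corrected normal approximation otherwise.
    """
    x, y = _clean(a), _clean(b)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    if test == "rank_sum":
        method = (
            "exact"
            if max(x.size, y.size) <= EXACT_RANKSUM_MAX_N
            and np.unique(np.concatenate([x, y])).size == x.size + y.size
            else "asymptotic"
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    elif test == "ks":
        res = sps.ks_2samp(x, y, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown test {test!r}; use 'rank_sum' or 'ks'")
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        effect={
            "mean1": float(np.mean(x)),
            "sd1": float(np.std(x, ddof=1)),
            "mean2": float(np.mean(y)),
            "sd2": float(np.std(y, ddof=1)),
        },
    )


def correlate(x, y) -> ComparisonResult:
    """Pearson correlation with two-tailed p and shared variance r^2 in %.

    Pairs with a missing member are dropped (pairwise-complete).
    """
    xv = np.asarray(list(x), float)
    yv = np.asarray(list(y), float)
    if xv.shape != yv.shape:
        raise ValueError("samples must have equal length")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined: a sample has zero variance")
    r, p = sps.pearsonr(xv, yv)
    return ComparisonResult(
        test="pearson",
        statistic=float(r),
        p_value=float(p),
        n1=int(xv.size),
        n2=int(yv.size),
        effect={"r": float(r), "r2_percent": float(100.0 * r * r)},
    )


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> ComparisonResult:
    """Pooled-variance two-sample t test from summary statistics.

    df = n1 + n2 - 2; two-tailed p from the t distribution.  Intended
    for comparisons where only mean, SD and n are published.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        test="t_from_summary",
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        n1=int(n1),
        n2=int(n2),
        effect={
            "mean1": float(mean1),
            "sd1": float(sd1),
            "mean2": float(mean2),
            "sd2": float(sd2),
            "df": float(df),
        },
    )
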