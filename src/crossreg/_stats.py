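"""Shared statistical primitives.

Thin wrappers around scipy with explicit small-sample conventions:
rank-sum tests switch to exact null distributions for small groups,
and Spearman p-values are computed by exhaustive permutation when the
sample is small enough to enumerate.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "rank_sum_test",
    "spearman_test",
    "fisher_greater",
    "sample_odds_ratio",
]

_EXACT_RANKSUM_MAX = 25
_EXACT_SPEARMAN_MAX = 8


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when both groups have <= 25 observations
    and there are no ties; otherwise the normal approximation with
    continuity correction.

    Returns ``(U, p)`` with U computed for `x` relative to `y`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    exact = (
        max(x.size, y.size) <= _EXACT_RANKSUM_MAX and not _has_ties(x, y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    return perms


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman correlation with an exact permutation p-value for small n.

    For n <= 8 with no ties in either vector the two-sided p-value is
    P(|rho_perm| >= |rho_obs|) over all n! rank permutations; otherwise
    scipy's asymptotic approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("spearman_test requires n >= 3")
    rho, p_asym = stats.spearmanr(x, y)
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= _EXACT_SPEARMAN_MAX and no_ties and np.isfinite(rho):
        rx = stats.rankdata(x)
        perms = _rank_permutations(n)
        d2 = ((perms - rx) ** 2).sum(axis=1)
        rho_all = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_asym)


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c), with inf when the denominator is 0."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact test on [[a, b], [c, d]].

    Returns the *sample* odds ratio (not the conditional MLE) and the
    hypergeometric tail p-value.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("negative cell count")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return sample_odds_ratio(a, b, c, d), float(p)
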