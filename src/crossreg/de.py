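"""Per-gene differential expression with permutation-calibrated FDR.

The FDR machinery follows a label-permutation scheme: group labels are
shuffled, the per-gene test is recomputed each round, and the reported
p-value cutoff is the largest one (on the grid of observed p-values) at
which the median permutation significant-gene count stays below the
target fraction of the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_greater
from .preprocessing import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "GeneEffect",
    "FdrCalibration",
    "test_differential",
    "effect_size",
    "calibrate_permutation_fdr",
    "consistent_de",
    "overlap_test",
]


@dataclass(frozen=True)
class GeneEffect:
    """Result of one gene's group contrast in one cohort."""

    gene: str
    p: float
    d: float
    direction: int  # sign of mean(level A) - mean(level B)
    cohort: str = ""


@dataclass
class FdrCalibration:
    """A permutation-calibrated p-value cutoff."""

    cutoff_p: float
    n_observed: int
    perm_counts: np.ndarray = field(repr=False)
    target_fdr: float
    n_perm: int
    seed: int
    p_grid: np.ndarray = field(repr=False)
    fdr_at_grid: np.ndarray = field(repr=False)
    attained: bool = True

    @property
    def median_perm_count(self) -> float:
        return float(np.median(self.perm_counts))


def _group_matrices(
    study: ExpressionStudy, contrast
) -> tuple[list[np.ndarray], list[str]]:
    levels = list(contrast)
    mats = []
    for lev in levels:
        cols = study.samples[study.group == lev]
        if len(cols) < 2:
            raise ValueError(f"contrast level {lev!r} has <2 samples")
        mats.append(study.values[cols].to_numpy(dtype=float))
    return mats, levels


def _t_pvalues(
    x1: np.ndarray,
    x2: np.ndarray,
    equal_var: bool = True,
    sided: str = "two",
) -> np.ndarray:
    """Row-wise two-sample t-test p-values with degenerate-row handling."""
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            x1, x2, axis=1, equal_var=equal_var, alternative=alternative
        )
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        diff = x1[bad].mean(axis=1) - x2[bad].mean(axis=1)
        fill = np.where(diff == 0, 1.0, 0.0)
        if sided == "greater":
            fill = np.where(diff > 0, 0.0, 1.0)
        elif sided == "less":
            fill = np.where(diff < 0, 0.0, 1.0)
        p[bad] = fill
    return p


def _anova_pvalues(mats: list[np.ndarray]) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*mats, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    if not p.shape:
        p = p.reshape(1)
    bad = ~np.isfinite(p)
    if bad.any():
        grand = np.hstack(mats)[bad]
        same = np.ptp(grand, axis=1) == 0
        p[bad] = np.where(same, 1.0, 0.0)
    return p


def _pvalues(mats, method: str, sided: str, equal_var: bool) -> np.ndarray:
    if method == "t":
        if len(mats) != 2:
            raise ValueError("t-test requires a two-level contrast")
        return _t_pvalues(mats[0], mats[1], equal_var=equal_var, sided=sided)
    if method == "anova":
        if sided != "two":
            raise ValueError("one-sided ANOVA is not defined")
        return _anova_pvalues(mats)
    raise ValueError(f"unknown method {method!r}")


def _effect_sizes(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    sd1 = x1.std(axis=1, ddof=1)
    sd2 = x2.std(axis=1, ddof=1)
    sdp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m2) / sdp
    zero = sdp == 0
    if zero.any():
        logger.warning("%d genes with zero pooled SD: d undefined", zero.sum())
        d[zero] = np.where(m1[zero] == m2[zero], 0.0, np.nan)
    return d


def effect_size(study: ExpressionStudy, level_a, level_b) -> pd.Series:
    """Pooled-SD standardized mean difference d = (M1 - M2) / SDp per gene.

    SDp uses the (N-1)-weighted pooled sample standard deviation. Genes
    whose pooled SD is zero get d = 0 when the means agree and NaN
    (reported missing) otherwise.
    """
    (x1, x2), _ = _group_matrices(study, (level_a, level_b))
    return pd.Series(_effect_sizes(x1, x2), index=study.genes, name="d")


def test_differential(
    study: ExpressionStudy,
    contrast,
    method: str = "t",
    sided: str = "two",
    equal_var: bool = True,
) -> list[GeneEffect]:
    """Per-gene group test. Two-level contrasts report effect size d too.

    For a pooled-variance t-test on two levels the p-value equals the
    one-way ANOVA p (F = t^2).
    """
    mats, levels = _group_matrices(study, contrast)
    p = _pvalues(mats, method, sided, equal_var)
    if len(mats) == 2:
        d = _effect_sizes(mats[0], mats[1])
        diff = mats[0].mean(axis=1) - mats[1].mean(axis=1)
        direction = np.sign(diff).astype(int)
    else:
        d = np.full(len(p), np.nan)
        direction = np.zeros(len(p), dtype=int)
    return [
        GeneEffect(g, float(pi), float(di), int(si), study.dataset)
        for g, pi, di, si in zip(study.genes, p, d, direction)
    ]


def calibrate_permutation_fdr(
    study: ExpressionStudy,
    contrast,
    method: str = "t",
    n_perm: int = 1000,
    target_fdr: float = 0.10,
    seed: int = 0,
    equal_var: bool = True,
) -> FdrCalibration:
    """Choose the largest p cutoff with permutation FDR <= `target_fdr`.

    Group labels of the contrasted samples are shuffled `n_perm` times
    (identity permutation excluded, duplicates allowed) and the per-gene
    test recomputed. The FDR estimate at cutoff c is
    median(perm significant count at c) / (observed count at c),
    monotonized by a running maximum over increasing cutoffs.
    """
    sub = study.subset_samples(
        study.samples[study.group.isin(list(contrast))]
    )
    labels = sub.group.to_numpy()
    x = sub.values.to_numpy(dtype=float)
    mask_a = labels == contrast[0]
    p_obs = _pvalues([x[:, mask_a], x[:, ~mask_a]], method, "two", equal_var)

    from math import comb

    n_a = int(mask_a.sum())
    n_distinct = comb(len(labels), n_a)
    if n_distinct - 1 < n_perm:
        logger.warning(
            "only %d distinct label permutations exist (< n_perm=%d)",
            n_distinct - 1,
            n_perm,
        )

    grid = np.unique(p_obs)
    obs_counts = np.searchsorted(np.sort(p_obs), grid, side="right")
    rng = np.random.default_rng(seed)
    perm_count_mat = np.empty((n_perm, len(grid)), dtype=np.int64)
    idx = np.arange(len(labels))
    for i in range(n_perm):
        while True:
            perm = rng.permutation(idx)
            if not np.array_equal(perm, idx):
                break
        pm = np.zeros(len(labels), dtype=bool)
        pm[perm[:n_a]] = True
        p_perm = _pvalues([x[:, pm], x[:, ~pm]], method, "two", equal_var)
        perm_count_mat[i] = np.searchsorted(np.sort(p_perm), grid, side="right")

    med = np.median(perm_count_mat, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = med / obs_counts
    fdr = np.maximum.accumulate(fdr)  # monotone non-decreasing in the cutoff
    ok = np.flatnonzero(fdr <= target_fdr)
    if len(ok) == 0:
        logger.warning(
            "no p cutoff attains FDR <= %.3g; returning empty significant set",
            target_fdr,
        )
        return FdrCalibration(
            cutoff_p=0.0,
            n_observed=0,
            perm_counts=perm_count_mat[:, 0] * 0,
            target_fdr=target_fdr,
            n_perm=n_perm,
            seed=seed,
            p_grid=grid,
            fdr_at_grid=fdr,
            attained=False,
        )
    j = int(ok[-1])
    # ties toward the smaller cutoff: same observed set -> keep smaller p
    while j > 0 and obs_counts[j - 1] == obs_counts[j] and fdr[j - 1] <= target_fdr:
        j -= 1
    return FdrCalibration(
        cutoff_p=float(grid[j]),
        n_observed=int(obs_counts[j]),
        perm_counts=perm_count_mat[:, j],
        target_fdr=target_fdr,
        n_perm=n_perm,
        seed=seed,
        p_grid=grid,
        fdr_at_grid=fdr,
    )


def consistent_de(
    a: list[GeneEffect],
    b: list[GeneEffect],
    rule: str = "fdr_both",
    cutoffs: dict | None = None,
) -> set[str]:
    """Genes passing the cutoff in both cohorts with the same direction.

    rule='fdr_both' uses per-cohort p cutoffs ``cutoffs={'p_a':…, 'p_b':…}``;
    rule='es_both' uses a shared effect-size cutoff ``cutoffs={'es':…}``.
    """
    cutoffs = cutoffs or {}
    ea = {g.gene: g for g in a}
    eb = {g.gene: g for g in b}
    shared = set(ea) & set(eb)
    if not shared:
        raise ValueError("no shared genes between effect lists")
    out = set()
    for gene in shared:
        ga, gb = ea[gene], eb[gene]
        if ga.direction == 0 or ga.direction != gb.direction:
            continue
        if rule == "fdr_both":
            if ga.p <= cutoffs["p_a"] and gb.p <= cutoffs["p_b"]:
                out.add(gene)
        elif rule == "es_both":
            es = cutoffs.get("es", 0.8)
            if (
                np.isfinite(ga.d)
                and np.isfinite(gb.d)
                and abs(ga.d) > es
                and abs(gb.d) > es
            ):
                out.add(gene)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return out


def overlap_test(
    set1: set, set2: set, background: set
) -> tuple[float, float]:
    """One-sided Fisher's exact test for overlap of two gene sets."""
    if not background:
        raise ValueError("empty background")
    if not (set(set1) <= set(background) and set(set2) <= set(background)):
        raise ValueError("sets must be subsets of the background")
    s1, s2, bg = set(set1), set(set2), set(background)
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(bg) - a - b - c
    return fisher_greater(a, b, c, d)
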