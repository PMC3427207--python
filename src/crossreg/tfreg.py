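"""TF regulatory-effect statistics.

The core statistic: a TF "regulates" the observed group differences if
its expression profile correlates more positively (or more negatively)
with its predicted targets than with other TFs' targets, among genes
passing the effect-size gate. Global significance comes from permuting
TF-target relationships; cross-cohort consistency from the Spearman
correlation of per-target correlation vectors (CoC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_greater, rank_sum_test, spearman_test
from .preprocessing import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "TFRegulon",
    "RegulatoryEffect",
    "CoCResult",
    "pearson_profile",
    "regulatory_effect_test",
    "scan_tf_regulators",
    "permute_regulon_labels",
    "correlation_of_correlations",
    "coc_global_significance",
    "common_candidate_excess",
]

MIN_TARGETS_DEFAULT = 5


@dataclass
class TFRegulon:
    """Predicted target set of one (TF, motif) pair."""

    tf: str
    motif: str
    targets: frozenset
    sites: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        if not self.targets:
            raise ValueError(f"regulon {self.tf}/{self.motif} has no targets")
        if self.tf in self.targets:
            raise ValueError(f"TF {self.tf} listed among its own targets")


@dataclass
class RegulatoryEffect:
    tf: str
    motif: str
    p: float
    direction: str  # 'more_positive' | 'more_negative'
    n_targets_tested: int
    n_nontargets: int
    median_target_r: float
    median_nontarget_r: float
    testable: bool = True

    def passes(self, alpha: float = 0.01) -> bool:
        return self.testable and self.p < alpha


@dataclass
class CoCResult:
    tf: str
    rho: float
    p: float
    n_shared_targets: int
    global_p: float | None = None
    testable: bool = True


def pearson_profile(study: ExpressionStudy, tf: str, genes) -> pd.Series:
    """Pearson r between the TF's profile and each listed gene, across all samples."""
    genes = pd.Index(genes)
    t = study.values.loc[tf].to_numpy(dtype=float)
    x = study.values.loc[genes].to_numpy(dtype=float)
    tc = t - t.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = xc @ tc / denom
    return pd.Series(r, index=genes, name=f"r({tf})")


def _split_eligible(
    regulon: TFRegulon, eligible: set, nontarget_pool: set | None
) -> tuple[list, list]:
    eligible = set(eligible) - {regulon.tf}
    targets = sorted(regulon.targets & eligible)
    if nontarget_pool is None:
        nontargets = sorted(eligible - regulon.targets)
    else:
        nontargets = sorted((set(nontarget_pool) & eligible) - regulon.targets - {regulon.tf})
    return targets, nontargets


def regulatory_effect_test(
    study: ExpressionStudy,
    regulon: TFRegulon,
    eligible: set,
    use_absolute: bool = False,
    min_targets: int = MIN_TARGETS_DEFAULT,
    nontarget_pool: set | None = None,
) -> RegulatoryEffect:
    """Rank-sum test of TF-target vs TF-non-target correlations.

    `eligible` is the effect-size-gated gene set; `nontarget_pool`, when
    given, restricts the background to genes that are targets of other
    TFs. With `use_absolute`, |r| replaces r on both sides.
    """
    targets, nontargets = _split_eligible(regulon, eligible, nontarget_pool)
    if len(targets) < min_targets or len(nontargets) < 1:
        return RegulatoryEffect(
            tf=regulon.tf,
            motif=regulon.motif,
            p=np.nan,
            direction="more_positive",
            n_targets_tested=len(targets),
            n_nontargets=len(nontargets),
            median_target_r=np.nan,
            median_nontarget_r=np.nan,
            testable=False,
        )
    r_t = pearson_profile(study, regulon.tf, targets).to_numpy()
    r_n = pearson_profile(study, regulon.tf, nontargets).to_numpy()
    if use_absolute:
        r_t, r_n = np.abs(r_t), np.abs(r_n)
    _, p = rank_sum_test(r_t, r_n, alternative="two-sided")
    med_t, med_n = float(np.median(r_t)), float(np.median(r_n))
    return RegulatoryEffect(
        tf=regulon.tf,
        motif=regulon.motif,
        p=p,
        direction="more_positive" if med_t >= med_n else "more_negative",
        n_targets_tested=len(targets),
        n_nontargets=len(nontargets),
        median_target_r=med_t,
        median_nontarget_r=med_n,
    )


def _target_pool(regulons: list[TFRegulon]) -> set:
    pool: set = set()
    for reg in regulons:
        pool |= set(reg.targets)
    return pool


def qualifying_regulons(
    regulons: list[TFRegulon],
    d: pd.Series,
    es_cutoff: float,
    expressed: set | None = None,
) -> list[TFRegulon]:
    """Regulons whose TF is expressed and passes the effect-size gate."""
    out = []
    for reg in regulons:
        if expressed is not None and reg.tf not in expressed:
            continue
        if reg.tf in d.index and np.isfinite(d[reg.tf]) and abs(d[reg.tf]) > es_cutoff:
            out.append(reg)
    return out


def scan_tf_regulators(
    study: ExpressionStudy,
    regulons: list[TFRegulon],
    d: pd.Series,
    es_cutoff: float = 0.8,
    alpha: float = 0.01,
    use_absolute: bool = False,
    min_targets: int = MIN_TARGETS_DEFAULT,
) -> list[RegulatoryEffect]:
    """Run the regulatory-effect test for every TF passing the |d| gate.

    `d` holds per-gene effect sizes; eligible genes satisfy |d| > es_cutoff.
    The non-target background is restricted to eligible genes annotated as
    targets of at least one other TF.
    """
    d = d.reindex(study.genes)
    eligible = set(d.index[np.abs(d.fillna(0.0)) > es_cutoff])
    qual = qualifying_regulons(regulons, d, es_cutoff, expressed=set(study.genes))
    if not qual:
        logger.info("no TFs pass the effect-size gate (|d| > %.2g)", es_cutoff)
        return []
    pool = _target_pool(regulons) & set(study.genes)
    results = []
    for reg in qual:
        res = regulatory_effect_test(
            study,
            reg,
            eligible,
            use_absolute=use_absolute,
            min_targets=min_targets,
            nontarget_pool=pool,
        )
        results.append(res)
    n_pass = sum(r.passes(alpha) for r in results)
    logger.info(
        "scan_tf_regulators: %d/%d regulons pass p<%.3g", n_pass, len(results), alpha
    )
    return results


def permute_regulon_labels(
    study: ExpressionStudy,
    regulons: list[TFRegulon],
    d: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    es_cutoff: float = 0.8,
    alpha: float = 0.01,
    min_targets: int = MIN_TARGETS_DEFAULT,
) -> tuple[float, float, np.ndarray]:
    """Global significance of the observed number of passing TFs.

    Target sets are reassigned at random (sizes preserved) among the
    eligible genes that are targets of at least one TF; the scan is
    repeated each round. Returns (global_p, expected_pass_count,
    per-permutation pass counts).
    """
    if len(regulons) < 2:
        raise ValueError("need >= 2 regulons to permute")
    d = d.reindex(study.genes)
    eligible = set(d.index[np.abs(d.fillna(0.0)) > es_cutoff])
    pool_all = _target_pool(regulons) & set(study.genes)
    pool = sorted(pool_all & eligible)
    qual = qualifying_regulons(regulons, d, es_cutoff, expressed=set(study.genes))
    observed = scan_tf_regulators(
        study, regulons, d, es_cutoff=es_cutoff, alpha=alpha, min_targets=min_targets
    )
    obs_pass = sum(r.passes(alpha) for r in observed)

    # precompute r(TF, gene) for every pooled eligible gene once per TF
    r_cache = {
        reg.tf: pearson_profile(study, reg.tf, pool).to_numpy() for reg in qual
    }
    pool_arr = np.array(pool)
    rng = np.random.default_rng(seed)
    pass_counts = np.zeros(n_perm, dtype=int)
    sizes = {
        (reg.tf, reg.motif): len(set(reg.targets) & (eligible - {reg.tf}))
        for reg in qual
    }
    for i in range(n_perm):
        n_pass = 0
        for reg in qual:
            k = sizes[(reg.tf, reg.motif)]
            if k < min_targets or k >= len(pool):
                continue
            r_all = r_cache[reg.tf]
            # mask out the TF itself if it sits in the pool
            valid = pool_arr != reg.tf
            idx_valid = np.flatnonzero(valid)
            pick = rng.choice(idx_valid, size=k, replace=False)
            is_t = np.zeros(len(pool_arr), dtype=bool)
            is_t[pick] = True
            r_t = r_all[is_t & valid]
            r_n = r_all[~is_t & valid]
            if len(r_n) < 1:
                continue
            _, p = rank_sum_test(r_t, r_n, alternative="two-sided")
            if p < alpha:
                n_pass += 1
        pass_counts[i] = n_pass
    global_p = float(np.mean(pass_counts >= obs_pass))
    return global_p, float(pass_counts.mean()), pass_counts


def correlation_of_correlations(
    a: ExpressionStudy,
    b: ExpressionStudy,
    regulon: TFRegulon,
    eligible_a: set,
    eligible_b: set,
) -> CoCResult:
    """Spearman correlation of per-target TF correlations across cohorts."""
    shared = sorted(
        (regulon.targets & set(eligible_a) & set(eligible_b))
        & set(a.genes)
        & set(b.genes)
    )
    if regulon.tf not in a.genes or regulon.tf not in b.genes:
        return CoCResult(regulon.tf, np.nan, np.nan, len(shared), testable=False)
    if len(shared) < 3:
        return CoCResult(regulon.tf, np.nan, np.nan, len(shared), testable=False)
    r_a = pearson_profile(a, regulon.tf, shared).to_numpy()
    r_b = pearson_profile(b, regulon.tf, shared).to_numpy()
    rho, p = spearman_test(r_a, r_b)
    return CoCResult(regulon.tf, rho, p, len(shared))


def coc_global_significance(
    a: ExpressionStudy,
    b: ExpressionStudy,
    regulons: list[TFRegulon],
    focal_tf: str,
    eligible_a: set,
    eligible_b: set,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, CoCResult]:
    """Permutation global p for the focal TF's cross-cohort CoC.

    The statistic is the number of TFs whose CoC p-value is at least as
    small as the focal TF's observed one; TF-target relations are
    permuted among genes eligible in both cohorts.
    """
    focal_regs = [r for r in regulons if r.tf == focal_tf]
    if not focal_regs:
        raise ValueError(f"no regulon for focal TF {focal_tf!r}")
    obs = min(
        (correlation_of_correlations(a, b, r, eligible_a, eligible_b)
         for r in focal_regs),
        key=lambda c: c.p if c.testable else np.inf,
    )
    if not obs.testable:
        return np.nan, obs
    results_all = [
        correlation_of_correlations(a, b, r, eligible_a, eligible_b)
        for r in regulons
    ]
    obs_count = sum(
        1 for c in results_all if c.testable and c.p <= obs.p + 1e-12
    )

    both = set(eligible_a) & set(eligible_b) & set(a.genes) & set(b.genes)
    pool = sorted(_target_pool(regulons) & both)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        n_hit = 0
        for reg in regulons:
            k = len(reg.targets & both)
            avail = [g for g in pool if g != reg.tf]
            if k < 3 or k > len(avail):
                continue
            fake_targets = frozenset(
                rng.choice(np.array(avail), size=k, replace=False)
            )
            fake = TFRegulon(reg.tf, reg.motif, fake_targets)
            c = correlation_of_correlations(a, b, fake, eligible_a, eligible_b)
            if c.testable and c.p <= obs.p + 1e-12:
                n_hit += 1
        if n_hit >= obs_count:
            count_ge += 1
    obs.global_p = float(count_ge / n_perm)
    return obs.global_p, obs


def common_candidate_excess(
    candidates_a: set, candidates_b: set, background_tfs: set
) -> tuple[float, float]:
    """One-sided Fisher's exact test for the overlap of candidate TF sets."""
    if not background_tfs:
        raise ValueError("empty TF background")
    if not (set(candidates_a) <= set(background_tfs)):
        raise ValueError("candidates_a not within background")
    if not (set(candidates_b) <= set(background_tfs)):
        raise ValueError("candidates_b not within background")
    a = len(set(candidates_a) & set(candidates_b))
    b = len(set(candidates_a) - set(candidates_b))
    c = len(set(candidates_b) - set(candidates_a))
    d = len(set(background_tfs)) - a - b - c
    return fisher_greater(a, b, c, d)
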