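"""Category over-representation with resampling FDR and global significance."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_greater

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryAnnotation",
    "EnrichmentResult",
    "ResamplingFdrResult",
    "category_enrichment",
    "resampling_fdr",
    "DEFAULT_P_GRID",
]

DEFAULT_P_GRID = (0.05, 0.01, 0.005, 0.001)


@dataclass
class CategoryAnnotation:
    """Many-to-many gene -> category mapping."""

    gene_to_cats: dict = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_to_cats = {
            g: frozenset(cats) for g, cats in self.gene_to_cats.items() if cats
        }
        cat_to_genes: dict = defaultdict(set)
        for g, cats in self.gene_to_cats.items():
            for c in cats:
                cat_to_genes[c].add(g)
        self.cat_to_genes = {c: frozenset(gs) for c, gs in cat_to_genes.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_col="gene", cat_col="category"):
        mapping: dict = defaultdict(set)
        for g, c in zip(df[gene_col], df[cat_col]):
            mapping[g].add(c)
        return cls(dict(mapping))

    def annotated(self, genes) -> set:
        return {g for g in genes if g in self.gene_to_cats}

    def category_sizes(self, universe=None) -> dict:
        if universe is None:
            return {c: len(gs) for c, gs in self.cat_to_genes.items()}
        universe = set(universe)
        return {c: len(gs & universe) for c, gs in self.cat_to_genes.items()}


@dataclass
class EnrichmentResult:
    category: str
    odds_ratio: float
    p: float
    n_test_in: int
    n_test: int
    n_bg_in: int
    n_bg: int


def category_enrichment(
    test_set: set,
    background: set,
    annotation: CategoryAnnotation,
    min_size: int = 10,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact test per category with >= `min_size` annotated genes.

    Only annotated genes enter the 2x2 tables; `test_set` and `background`
    must be disjoint.
    """
    test_set, background = set(test_set), set(background)
    if test_set & background:
        raise ValueError("test set and background overlap")
    t_ann = annotation.annotated(test_set)
    b_ann = annotation.annotated(background)
    if not t_ann or not b_ann:
        logger.warning("no annotated genes in test set or background")
        return []
    universe = t_ann | b_ann
    sizes = annotation.category_sizes(universe)
    results = []
    for cat, size in sorted(sizes.items()):
        if size < min_size:
            continue
        members = annotation.cat_to_genes[cat]
        a = len(t_ann & members)
        b = len(t_ann) - a
        c = len(b_ann & members)
        d = len(b_ann) - c
        orr, p = fisher_greater(a, b, c, d)
        results.append(EnrichmentResult(cat, orr, p, a, len(t_ann), c, len(b_ann)))
    return results


@dataclass
class ResamplingFdrResult:
    p_grid: tuple
    observed_counts: dict
    observed_freq: dict
    fdr: dict  # cutoff -> FDR estimate or None (undefined when observed 0)
    global_p: dict  # cutoff -> permutation p
    n_categories_tested: int
    n_resample: int
    seed: int
    reporting_cutoff: float | None = None


def _enriched_counts(results: list[EnrichmentResult], p_grid) -> dict:
    ps = np.array([r.p for r in results])
    return {c: int((ps < c).sum()) for c in p_grid}


def resampling_fdr(
    test_set: set,
    background: set,
    annotation: CategoryAnnotation,
    n_resample: int = 1000,
    p_grid=DEFAULT_P_GRID,
    seed: int = 0,
    min_size: int = 10,
) -> ResamplingFdrResult:
    """Resampling FDR and global p for category enrichment.

    Sets of the test set's size are redrawn from the annotated background
    `n_resample` times; at each cutoff FDR = median resampled enriched-
    category frequency / observed frequency, and global p = fraction of
    resamples with at least as many enriched categories as observed.
    The reporting cutoff is the largest grid value with FDR < 0.10 and
    global p < 0.05.
    """
    test_set, background = set(test_set), set(background)
    obs_results = category_enrichment(test_set, background, annotation, min_size)
    obs_counts = _enriched_counts(obs_results, p_grid)
    n_cats = len(obs_results)

    bg_ann = sorted(annotation.annotated(background))
    n_draw = len(annotation.annotated(test_set))
    if n_draw > len(bg_ann):
        raise ValueError("test set larger than annotated background")
    rng = np.random.default_rng(seed)
    bg_arr = np.array(bg_ann)
    perm_counts = {c: np.zeros(n_resample, dtype=int) for c in p_grid}
    for i in range(n_resample):
        fake = set(rng.choice(bg_arr, size=n_draw, replace=False))
        res = category_enrichment(fake, background - fake, annotation, min_size)
        for c, n in _enriched_counts(res, p_grid).items():
            perm_counts[c][i] = n

    fdr: dict = {}
    global_p: dict = {}
    obs_freq: dict = {}
    for c in p_grid:
        obs = obs_counts[c]
        obs_freq[c] = obs / n_cats if n_cats else np.nan
        med = float(np.median(perm_counts[c]))
        fdr[c] = None if obs == 0 else med / obs
        global_p[c] = float(np.mean(perm_counts[c] >= obs))
    reporting = None
    for c in sorted(p_grid, reverse=True):
        if fdr[c] is not None and fdr[c] < 0.10 and global_p[c] < 0.05:
            reporting = c
            break
    return ResamplingFdrResult(
        p_grid=tuple(p_grid),
        observed_counts=obs_counts,
        observed_freq=obs_freq,
        fdr=fdr,
        global_p=global_p,
        n_categories_tested=n_cats,
        n_resample=n_resample,
        seed=seed,
        reporting_cutoff=reporting,
    )
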