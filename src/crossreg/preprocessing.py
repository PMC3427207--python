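"""Expression-matrix preprocessing.

Normalization, detection filtering, batch-mean removal, and cross-cohort
combination by two-stage standardization. All operations are pure: they
return a new :class:`ExpressionStudy` and never mutate their input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "quantile_normalize",
    "log_quantile_normalize",
    "filter_detected",
    "remove_batch_effect",
    "standardize_and_combine",
]


@dataclass
class ExpressionStudy:
    """A gene x sample expression matrix with per-sample labels.

    Parameters
    ----------
    values:
        Genes in rows, samples in columns (log2 scale once normalized).
    group:
        Per-sample categorical label (indexed by sample id).
    batch:
        Optional per-sample batch label.
    dataset:
        Cohort identifier.
    detection_p:
        Optional gene x sample matrix of detection p-values.
    """

    values: pd.DataFrame
    group: pd.Series
    batch: pd.Series | None = None
    dataset: str = ""
    detection_p: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        self.group = pd.Series(self.group).reindex(self.values.columns)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise ValueError(f"samples without group label: {missing}")
        if self.batch is not None:
            self.batch = pd.Series(self.batch).reindex(self.values.columns)
            if self.batch.isna().any():
                raise ValueError("samples without batch label")
        if self.detection_p is not None:
            dp = self.detection_p
            if not (
                dp.index.equals(self.values.index)
                and dp.columns.equals(self.values.columns)
            ):
                raise ValueError("detection_p must align with values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionStudy":
        genes = pd.Index(genes)
        dp = None if self.detection_p is None else self.detection_p.loc[genes]
        return replace(self, values=self.values.loc[genes], detection_p=dp)

    def subset_samples(self, samples) -> "ExpressionStudy":
        samples = pd.Index(samples)
        dp = None if self.detection_p is None else self.detection_p[samples]
        return ExpressionStudy(
            values=self.values[samples],
            group=self.group[samples],
            batch=None if self.batch is None else self.batch[samples],
            dataset=self.dataset,
            detection_p=dp,
        )


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every column shares one value multiset.

    The reference distribution is the row-wise mean of the column-sorted
    matrix. Tied values within a column receive the mean of the reference
    quantiles at their rank positions.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # tied input values receive the mean of their reference quantiles
        if np.unique(col).size < n:
            assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def log_quantile_normalize(
    study: ExpressionStudy, pseudocount: float = 0.0
) -> ExpressionStudy:
    """log2(x + pseudocount), then quantile normalization across samples."""
    if study.n_samples < 2:
        raise ValueError("cannot quantile-normalize a single-sample study")
    vals = study.values.to_numpy(dtype=float)
    if pseudocount > 0 and (vals < 0).any():
        raise ValueError("negative values with a pseudocount transform")
    logged = pd.DataFrame(
        np.log2(vals + pseudocount) if pseudocount else np.log2(vals),
        index=study.genes,
        columns=study.samples,
    )
    return replace(study, values=quantile_normalize(logged))


def _uneven_detection_p(detected: np.ndarray, groups: np.ndarray) -> float:
    """Test detected/undetected counts for unevenness across groups."""
    levels = np.unique(groups)
    table = np.array(
        [
            [int(detected[groups == g].sum()), int((~detected[groups == g]).sum())]
            for g in levels
        ]
    )
    if len(levels) == 2:
        (a, b), (c, d) = table
        # two-sided version of the exact test: unevenness in either direction
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p)
    if table.sum(axis=0).min() == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p, _, _ = stats.chi2_contingency(table + 0.5)
    return float(p)


def filter_detected(
    study: ExpressionStudy,
    detect_alpha: float = 0.05,
    uneven_alpha: float = 0.1,
    counts: bool = False,
) -> ExpressionStudy:
    """Keep genes that are reliably detected or group-specifically detected.

    A gene is retained if (1) it is detected (detection p < `detect_alpha`,
    or count > 0 in count mode) in at least half of the samples, or (2) its
    detected/undetected split is uneven across groups at `uneven_alpha`.
    In count mode genes with zero counts in more than half of the samples
    are always dropped.
    """
    if counts:
        detected = study.values.to_numpy() > 0
    elif study.detection_p is not None:
        detected = study.detection_p.to_numpy() < detect_alpha
    else:
        raise ValueError(
            "no detection information: detection_p missing and counts=False "
            f"for all {study.n_genes} genes"
        )
    n = study.n_samples
    groups = study.group.to_numpy()
    crit1 = detected.sum(axis=1) >= n / 2.0
    keep = crit1.copy()
    for i in np.flatnonzero(~crit1):
        row = detected[i]
        if row.any() and not row.all():
            keep[i] = _uneven_detection_p(row, groups) < uneven_alpha
    if counts:
        keep &= crit1  # zero in more than half of samples -> always dropped
    kept = study.genes[keep]
    logger.info(
        "filter_detected: %d of %d genes retained", len(kept), study.n_genes
    )
    return study.subset_genes(kept)


def remove_batch_effect(study: ExpressionStudy) -> ExpressionStudy:
    """Subtract each batch's per-gene mean from samples in that batch."""
    if study.batch is None:
        raise ValueError("batch labels required")
    vals = study.values.copy()
    for b, cols in study.values.columns.groupby(study.batch).items():
        cols = pd.Index(cols)
        if len(cols) == 1:
            logger.warning(
                "batch %r has a single sample; it is centered to 0", b
            )
        vals[cols] = vals[cols].sub(vals[cols].mean(axis=1), axis=0)
    return replace(study, values=vals)


def _zscore_rows(
    df: pd.DataFrame, scale_cols: pd.Index
) -> tuple[pd.DataFrame, pd.Index]:
    mu = df[scale_cols].mean(axis=1)
    sd = df[scale_cols].std(axis=1, ddof=1)
    bad = df.index[(sd == 0) | sd.isna()]
    z = df.sub(mu, axis=0).div(sd, axis=0)
    return z, bad


def standardize_and_combine(
    a: ExpressionStudy,
    b: ExpressionStudy,
    groups_for_scaling: set | None = None,
) -> ExpressionStudy:
    """Combine two cohorts on shared genes via two-stage z-scoring.

    Stage 1 z-scores each gene within each cohort using the samples whose
    group is in `groups_for_scaling` (all samples when None); stage 2
    z-scores each gene across all combined samples. Genes with zero
    variance in either cohort are dropped with a warning.
    """
    shared = a.genes.intersection(b.genes)
    if len(shared) == 0:
        raise ValueError("no shared genes between cohorts")
    if set(a.samples) & set(b.samples):
        raise ValueError("cohorts share sample identifiers")
    parts, groups = [], []
    dropped: set = set()
    for study in (a, b):
        vals = study.values.loc[shared]
        if groups_for_scaling is None:
            cols = study.samples
        else:
            cols = study.samples[study.group.isin(groups_for_scaling)]
            if len(cols) < 2:
                raise ValueError(
                    f"cohort {study.dataset!r}: <2 samples in scaling groups"
                )
        z, bad = _zscore_rows(vals, pd.Index(cols))
        dropped.update(bad)
        parts.append(z)
        groups.append(study.group)
    if dropped:
        logger.warning(
            "dropping %d zero-variance genes during combination", len(dropped)
        )
        keep = shared.difference(pd.Index(sorted(dropped)))
        parts = [p.loc[keep] for p in parts]
        shared = keep
    combined = pd.concat(parts, axis=1)
    stage2, bad2 = _zscore_rows(combined, combined.columns)
    if len(bad2):
        stage2 = stage2.drop(index=bad2)
    return ExpressionStudy(
        values=stage2,
        group=pd.concat(groups),
        batch=None,
        dataset=f"{a.dataset}+{b.dataset}",
    )
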