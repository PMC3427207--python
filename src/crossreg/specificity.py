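"""Focal-tissue specificity z-scores and cross-species comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "TissueAtlas",
    "SpecificityResult",
    "specificity_z",
    "compare_specificity",
    "relative_within_tissue_level",
]


@dataclass
class TissueAtlas:
    """Gene x tissue expression matrix for one species."""

    values: pd.DataFrame
    species: str
    focal_tissue: str

    def __post_init__(self) -> None:
        if self.focal_tissue not in self.values.columns:
            raise ValueError(
                f"focal tissue {self.focal_tissue!r} not in atlas columns"
            )
        if self.values.shape[1] < 3:
            raise ValueError("atlas needs >= 3 tissues")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")


@dataclass
class SpecificityResult:
    z1: pd.Series
    z2: pd.Series
    shift_applied: float
    p: float
    n_foreground: int


def specificity_z(atlas: TissueAtlas) -> pd.Series:
    """z = (focal - mean over tissues) / SD over tissues, per gene.

    Genes constant across tissues get NaN (undefined) with a warning.
    """
    vals = atlas.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals[atlas.focal_tissue] - mu) / sd
    n_bad = int((sd == 0).sum())
    if n_bad:
        logger.warning(
            "%s: %d genes constant across tissues; z undefined", atlas.species, n_bad
        )
        z[sd == 0] = np.nan
    return z.rename(f"z_{atlas.species}")


def compare_specificity(
    z_a: pd.Series,
    z_b: pd.Series,
    foreground: set,
    background: set,
    alternative: str = "greater",
) -> SpecificityResult:
    """Background-aligned one-sided rank-sum test of a foreground z shift.

    z_b is shifted so the background medians of both species coincide
    exactly, then foreground z_b vs z_a are compared with the stated
    alternative ('greater' tests z_b > z_a after alignment).
    """
    foreground, background = set(foreground), set(background)
    if foreground & background:
        raise ValueError("foreground and background overlap")
    if not foreground or not background:
        raise ValueError("empty foreground or background")
    shared = z_a.index.intersection(z_b.index)
    ok = shared[np.isfinite(z_a[shared]) & np.isfinite(z_b[shared])]
    fg = [g for g in ok if g in foreground]
    bg = [g for g in ok if g in background]
    if not fg or not bg:
        raise ValueError("no usable foreground/background genes after NaN drop")
    shift = float(np.median(z_a[bg]) - np.median(z_b[bg]))
    z_b_aligned = z_b + shift
    _, p = rank_sum_test(
        z_b_aligned[fg].to_numpy(), z_a[fg].to_numpy(), alternative=alternative
    )
    return SpecificityResult(
        z1=z_a[ok], z2=z_b_aligned[ok], shift_applied=shift, p=p, n_foreground=len(fg)
    )


def relative_within_tissue_level(levels: pd.Series) -> pd.Series:
    """z-score each gene's level against all genes within one tissue."""
    if len(levels) < 3:
        raise ValueError("need >= 3 genes")
    mu = levels.mean()
    sd = levels.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across genes")
    return (levels - mu) / sd
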