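import numpy as np
import pandas as pd
import pytest

from crossreg.motif import PWM
from crossreg.preprocessing import ExpressionStudy


def make_study(
    values: np.ndarray,
    groups,
    genes=None,
    batches=None,
    dataset: str = "test",
    detection_p=None,
) -> ExpressionStudy:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    dp = (
        pd.DataFrame(np.asarray(detection_p, dtype=float), index=genes, columns=samples)
        if detection_p is not None
        else None
    )
    return ExpressionStudy(
        values=df,
        group=pd.Series(list(groups), index=samples),
        batch=pd.Series(list(batches), index=samples) if batches is not None else None,
        dataset=dataset,
        detection_p=dp,
    )


def null_study(n_genes, n_per_group, seed=0, dataset="null") -> ExpressionStudy:
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_genes, 2 * n_per_group))
    return make_study(vals, ["g1"] * n_per_group + ["g2"] * n_per_group, dataset=dataset)


@pytest.fixture
def gc_rich_pwm() -> PWM:
    """A 14-bp G/C-rich matrix with a 5-bp all-G core (positions 6-10)."""
    rows = []
    for i, base in enumerate("GCGCAGGGGGCGGC"):
        row = [1.0, 1.0, 1.0, 1.0]
        row["ACGT".index(base)] = 20.0
        rows.append(row)
    return PWM("M_GC14", np.array(rows), core=(6, 10))


@pytest.fixture
def small_pwm() -> PWM:
    rows = []
    for base in "ACGTAC":
        row = [0.5, 0.5, 0.5, 0.5]
        row["ACGT".index(base)] = 10.0
        rows.append(row)
    return PWM("M_SMALL", np.array(rows), core=(2, 5))
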