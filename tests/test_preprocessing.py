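import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crossreg.preprocessing import (
    ExpressionStudy,
    filter_detected,
    log_quantile_normalize,
    quantile_normalize,
    remove_batch_effect,
    standardize_and_combine,
)

from .conftest import make_study


class TestExpressionStudy:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            make_study(np.ones((2, 4)), ["a"] * 2 + ["b"] * 2, genes=["g", "g"])

    def test_group_must_cover_samples(self):
        df = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"], columns=list("abc"))
        with pytest.raises(ValueError, match="without group label"):
            ExpressionStudy(values=df, group=pd.Series({"a": "x", "b": "y"}))

    def test_subsetting_preserves_order(self):
        study = make_study(np.arange(12).reshape(3, 4), ["a", "a", "b", "b"])
        sub = study.subset_genes(["g2", "g0"])
        assert list(sub.genes) == ["g2", "g0"]
        sub2 = study.subset_samples(["s3", "s1"])
        assert list(sub2.group) == ["b", "a"]


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        study = make_study(
            np.column_stack([[1.0, 2.0, 4.0]] * 3), ["a", "a", "b"]
        )
        out = log_quantile_normalize(study, pseudocount=0.0)
        expected = np.log2(study.values.to_numpy())
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_two_column_hand_case(self):
        # columns [1,2,3] and [4,5,6]: after log2, every rank position
        # becomes the mean of the two sorted log columns
        study = make_study(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), ["a", "b"])
        out = log_quantile_normalize(study, pseudocount=0.0)
        ref = (np.log2([1.0, 2.0, 3.0]) + np.log2([4.0, 5.0, 6.0])) / 2
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], ref)
        np.testing.assert_allclose(out.values.to_numpy()[:, 1], ref)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 4)) ** 2 + 1)
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_permuted_columns_map_to_shared_vector(self):
        base = np.array([5.0, 1.0, 3.0, 2.0])
        df = pd.DataFrame({"a": base, "b": base[[2, 0, 3, 1]]})
        out = quantile_normalize(df)
        # rank preservation: each column is the same permutation of one vector
        assert list(out["a"].rank()) == list(pd.Series(base).rank())
        np.testing.assert_allclose(sorted(out["a"]), sorted(out["b"]))

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            np.float64,
            (8, 3),
            elements=st.floats(0.1, 1e3, allow_nan=False),
            unique=True,  # exact idempotence holds for tie-free matrices
        )
    )
    def test_property_idempotence(self, x):
        df = pd.DataFrame(x)
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_single_sample_error(self):
        study = make_study(np.ones((3, 1)), ["a"])
        with pytest.raises(ValueError, match="single-sample"):
            log_quantile_normalize(study)


class TestFilterDetected:
    def test_detected_everywhere_retained(self):
        dp = np.full((1, 6), 0.01)
        study = make_study(np.ones((1, 6)), ["a"] * 3 + ["b"] * 3, detection_p=dp)
        out = filter_detected(study)
        assert list(out.genes) == ["g0"]

    def test_group_specific_detection_retained(self):
        # detected in all of group A, none of group B: maximal unevenness
        dp = np.array([[0.01] * 4 + [0.9] * 4])
        study = make_study(np.ones((1, 8)), ["a"] * 4 + ["b"] * 4, detection_p=dp)
        out = filter_detected(study, uneven_alpha=0.1)
        assert list(out.genes) == ["g0"]

    def test_rarely_detected_dropped(self):
        # detected in 1 of 12 samples, evenly split across groups
        dp = np.full((1, 12), 0.9)
        dp[0, 0] = 0.01
        study = make_study(np.ones((1, 12)), ["a"] * 6 + ["b"] * 6, detection_p=dp)
        out = filter_detected(study)
        assert len(out.genes) == 0

    def test_count_mode_majority_zero_dropped(self):
        vals = np.array([[0, 0, 0, 0, 5, 6], [3, 1, 2, 8, 5, 6]], dtype=float)
        study = make_study(vals, ["a"] * 3 + ["b"] * 3)
        out = filter_detected(study, counts=True)
        assert list(out.genes) == ["g1"]

    def test_missing_detection_info_errors(self):
        study = make_study(np.ones((2, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="no detection information"):
            filter_detected(study)


class TestRemoveBatchEffect:
    def test_single_batch_centers_genes(self):
        vals = np.array([[1.0, 2.0, 3.0, 6.0]])
        study = make_study(vals, ["a", "a", "b", "b"], batches=["x"] * 4)
        out = remove_batch_effect(study)
        np.testing.assert_allclose(out.values.to_numpy(), [[-2.0, -1.0, 0.0, 3.0]])

    def test_equal_batch_means_hand_case(self):
        # two batches with equal gene means: output = input - global mean
        vals = np.array([[1.0, 3.0, 0.0, 4.0]])  # both batch means = 2
        study = make_study(vals, ["a", "b", "a", "b"], batches=["x", "x", "y", "y"])
        out = remove_batch_effect(study)
        np.testing.assert_allclose(out.values.to_numpy(), [[-1.0, 1.0, -2.0, 2.0]])

    def test_per_batch_means_zero(self):
        rng = np.random.default_rng(3)
        study = make_study(
            rng.normal(size=(20, 8)),
            ["a"] * 4 + ["b"] * 4,
            batches=["x", "y", "x", "y"] * 2,
        )
        out = remove_batch_effect(study)
        for b in ("x", "y"):
            cols = out.samples[out.batch == b]
            np.testing.assert_allclose(
                out.values[cols].mean(axis=1), 0.0, atol=1e-12
            )

    def test_requires_batch_labels(self):
        study = make_study(np.ones((2, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="batch labels"):
            remove_batch_effect(study)


class TestStandardizeAndCombine:
    def test_identical_cohorts(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 6))
        a = make_study(vals, ["x"] * 3 + ["y"] * 3, dataset="a")
        b = ExpressionStudy(
            values=pd.DataFrame(
                vals, index=a.genes, columns=[f"t{i}" for i in range(6)]
            ),
            group=pd.Series(["x"] * 3 + ["y"] * 3, index=[f"t{i}" for i in range(6)]),
            dataset="b",
        )
        out = standardize_and_combine(a, b)
        # each row of the combined matrix is the cohort z-score repeated,
        # rescaled to unit SD over 12 samples
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        tiled = np.hstack([z, z])
        tiled = tiled / tiled.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(out.values.to_numpy(), tiled, atol=1e-10)

    def test_rows_are_standardized(self):
        a = make_study(np.random.default_rng(5).normal(size=(8, 4)), ["x", "x", "y", "y"], dataset="a")
        bvals = np.random.default_rng(6).normal(size=(8, 6))
        b = ExpressionStudy(
            values=pd.DataFrame(bvals, index=a.genes, columns=[f"t{i}" for i in range(6)]),
            group=pd.Series(["x"] * 3 + ["y"] * 3, index=[f"t{i}" for i in range(6)]),
            dataset="b",
        )
        out = standardize_and_combine(a, b)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_gene_dropped(self):
        vals = np.random.default_rng(7).normal(size=(3, 4))
        vals[1] = 5.0
        a = make_study(vals, ["x", "x", "y", "y"], dataset="a")
        b = ExpressionStudy(
            values=pd.DataFrame(
                np.random.default_rng(8).normal(size=(3, 4)),
                index=a.genes,
                columns=[f"t{i}" for i in range(4)],
            ),
            group=pd.Series(["x", "x", "y", "y"], index=[f"t{i}" for i in range(4)]),
            dataset="b",
        )
        out = standardize_and_combine(a, b)
        assert "g1" not in out.genes
        assert {"g0", "g2"} == set(out.genes)

    def test_no_shared_genes_errors(self):
        a = make_study(np.ones((2, 4)), ["x", "x", "y", "y"], genes=["g1", "g2"])
        b = make_study(np.ones((2, 4)), ["x", "x", "y", "y"], genes=["h1", "h2"])
        with pytest.raises(ValueError, match="share sample|shared genes"):
            standardize_and_combine(a, b)
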