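import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossreg.motif import (
    PWM,
    BindingSite,
    GenomicInterval,
    PromoterRecord,
    binding_site_null,
    compare_score_distributions,
    conservation_filter,
    dinucleotide_shuffle,
    dnase_overlap_test,
    predict_regulons,
    reverse_complement,
    scan_pwm,
    shuffle_conservation,
    tss_proximity_test,
)
from crossreg.synthetic import generate_dnase_tracks, generate_promoters

from .oracles import dinucleotide_counts, ks_one_sided_exact, wilcoxon_two_sided_exact

DNA = st.text(alphabet="ACGT", min_size=2, max_size=300)


def flat_promoter(seq, cons=None, gene="g", tss=None):
    return PromoterRecord(
        gene=gene,
        tss_offset=len(seq) // 2 if tss is None else tss,
        sequence=seq,
        conservation=cons,
    )


class TestPWM:
    def test_consensus(self, small_pwm):
        assert small_pwm.consensus == "ACGTAC"

    def test_core_bounds_checked(self):
        with pytest.raises(ValueError, match="core"):
            PWM("m", np.ones((4, 4)), core=(0, 4))

    def test_row_sum_positive(self):
        counts = np.ones((3, 4))
        counts[1] = 0
        with pytest.raises(ValueError, match="positive count sum"):
            PWM("m", counts)

    def test_reverse_complement_roundtrip(self, small_pwm):
        rc = small_pwm.reverse_complement()
        assert rc.consensus == reverse_complement(small_pwm.consensus)
        back = rc.reverse_complement()
        np.testing.assert_array_equal(back.counts, small_pwm.counts)
        assert back.core == small_pwm.core


class TestScanPwm:
    def test_consensus_scores_one(self, small_pwm):
        seq = "TTTT" + small_pwm.consensus + "TTTT"
        sites = scan_pwm(flat_promoter(seq), small_pwm, 0.99, 0.99)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].score == pytest.approx(1.0)
        assert plus[0].start == 4 - len(seq) // 2

    def test_reverse_complement_reported_on_minus(self, small_pwm):
        word = reverse_complement(small_pwm.consensus)
        seq = "TTTTT" + word + "TTTTT"
        sites = scan_pwm(flat_promoter(seq), small_pwm, 0.99, 0.99)
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1
        assert minus[0].start == 5 - len(seq) // 2
        assert minus[0].score == pytest.approx(1.0)

    def test_uniform_pwm_all_positions_equal(self):
        pwm = PWM("flat", np.full((4, 4), 2.0))
        seq = "ACGTACGTACGT"
        sites = scan_pwm(flat_promoter(seq), pwm, min_score=0.0, min_core_score=0.0)
        scores = {s.score for s in sites}
        assert len(scores) == 1
        # zero information vector: min-max window collapses; defined as 1
        assert scores == {1.0}

    def test_n_windows_skipped(self, small_pwm):
        seq = "TT" + small_pwm.consensus[:3] + "N" + small_pwm.consensus[4:] + "TT"
        sites = scan_pwm(flat_promoter(seq), small_pwm, 0.0, 0.0)
        starts = {s.start + len(seq) // 2 for s in sites}
        for j in range(2, 8):  # windows covering the N
            assert j not in starts

    def test_short_promoter_errors(self, small_pwm):
        with pytest.raises(ValueError, match="shorter than PWM"):
            scan_pwm(flat_promoter("ACG"), small_pwm)

    def test_score_formula_hand_case(self):
        # 2-position matrix; verify the normalized MATCH similarity directly
        counts = np.array([[8.0, 1.0, 1.0, 1.0], [1.0, 8.0, 1.0, 1.0]])
        pwm = PWM("m2", counts)
        f = (counts + 0.25) / (counts + 0.25).sum(axis=1, keepdims=True)
        info = (f * np.log(4 * f)).sum(axis=1)
        s = info[:, None] * f
        raw_ac = s[0, 0] + s[1, 1]
        raw_gg = s[0, 2] + s[1, 2]
        lo, hi = s.min(axis=1).sum(), s.max(axis=1).sum()
        sites = scan_pwm(flat_promoter("AC"), pwm, min_score=0.0, min_core_score=0.0)
        plus = [x for x in sites if x.strand == "+"]
        assert plus[0].score == pytest.approx((raw_ac - lo) / (hi - lo), abs=1e-12)
        assert plus[0].score == pytest.approx(1.0)
        sites_gg = scan_pwm(flat_promoter("GG"), pwm, 0.0, 0.0)
        plus_gg = [x for x in sites_gg if x.strand == "+"]
        assert plus_gg[0].score == pytest.approx((raw_gg - lo) / (hi - lo), abs=1e-12)


class TestConservationFilter:
    def _site(self, coverage, mean):
        return BindingSite("g", 0, "+", 1.0, 14, 1.0, coverage, mean)

    def test_full_coverage_passes(self):
        assert conservation_filter(self._site(1.0, 0.7))

    def test_low_coverage_fails_regardless_of_mean(self):
        assert not conservation_filter(self._site(10 / 14, 0.99))

    def test_boundary_inclusive(self):
        assert conservation_filter(self._site(0.8, 0.6))


class TestPredictRegulons:
    def test_planted_targets_recovered(self, gc_rich_pwm):
        planted = [(i, -100, "+") for i in range(23)]
        promoters = generate_promoters(40, 1000, planted, gc_rich_pwm, gc=0.4, seed=5)
        regulons = predict_regulons(promoters, [gc_rich_pwm], {gc_rich_pwm.id: "tf1"})
        assert len(regulons) == 1
        expected = {f"g{i:04d}" for i in range(23)}
        assert set(regulons[0].targets) == expected

    def test_unconserved_sites_excluded(self, gc_rich_pwm):
        promoters = generate_promoters(5, 600, [(0, -50, "+")], gc_rich_pwm, seed=6)
        # overwrite conservation at the planted site with low scores
        prom = promoters[0]
        a = prom.tss_offset - 50
        prom.conservation[a : a + gc_rich_pwm.width] = 0.3
        regulons = predict_regulons(promoters, [gc_rich_pwm], {gc_rich_pwm.id: "tf1"})
        assert regulons == []

    def test_no_planted_no_regulons(self, gc_rich_pwm):
        promoters = generate_promoters(10, 600, [], gc_rich_pwm, gc=0.4, seed=7)
        regulons = predict_regulons(promoters, [gc_rich_pwm], {gc_rich_pwm.id: "tf1"})
        assert regulons == []


class TestTssProximity:
    def _sites(self, dists):
        return [BindingSite("g", int(d), "+", 1.0, 14) for d in dists]

    def test_all_at_tss_minimal_p(self):
        p, med = tss_proximity_test(self._sites([0] * 20), half_window=2000)
        assert med == 0
        assert p < 1e-6

    def test_uniform_null(self):
        rng = np.random.default_rng(8)
        ps = [
            tss_proximity_test(
                self._sites(rng.integers(0, 2000, 30)), half_window=2000
            )[0]
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_exact_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            dists = [int(d) for d in rng.uniform(0, 2000, n)]
            p, _ = tss_proximity_test(self._sites(dists), half_window=2000)
            _, p_oracle = ks_one_sided_exact(dists, lambda x: min(1.0, x / 2000))
            assert p == pytest.approx(p_oracle, abs=1e-6)


class TestDinucleotideShuffle:
    def test_aaaa_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_acgt_fixed_point(self):
        # only one permutation preserves {AC, CG, GT}
        assert dinucleotide_shuffle("ACGT", seed=1) == "ACGT"

    def test_counts_preserved_random_inputs(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(2, 500))
            seq = "".join(rng.choice(list("ACGT"), n))
            out = dinucleotide_shuffle(seq, seed=int(rng.integers(1 << 31)))
            assert dinucleotide_counts(out) == dinucleotide_counts(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]

    @settings(max_examples=50, deadline=None)
    @given(DNA, st.integers(0, 2**31 - 1))
    def test_property_counts_and_endpoints(self, seq, seed):
        out = dinucleotide_shuffle(seq, seed=seed)
        assert len(out) == len(seq)
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]


class TestShuffleConservation:
    def test_all_same_base_permutes_scores(self):
        cons = np.arange(6, dtype=float) / 10
        prom = flat_promoter("AAAAAA", cons=cons)
        out = shuffle_conservation(prom, seed=3)
        assert sorted(out) == sorted(cons)

    def test_per_base_multisets_preserved(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 400))
        cons = rng.uniform(0, 1, 400)
        prom = flat_promoter(seq, cons=cons)
        out = shuffle_conservation(prom, seed=4)
        for b in "ACGT":
            idx = [i for i, c in enumerate(seq) if c == b]
            assert sorted(out[idx]) == pytest.approx(sorted(cons[idx]))

    def test_singleton_base_unchanged(self):
        seq = "AACAA"
        cons = np.array([0.1, 0.2, 0.9, 0.4, 0.5])
        out = shuffle_conservation(flat_promoter(seq, cons=cons), seed=5)
        assert out[2] == 0.9

    def test_missing_track_errors(self):
        with pytest.raises(ValueError, match="no conservation"):
            shuffle_conservation(flat_promoter("ACGT"), seed=0)


class TestBindingSiteNull:
    def test_planted_signal_destroyed_by_shuffle(self, gc_rich_pwm):
        planted = [(i, -60, "+") for i in range(12)]
        promoters = generate_promoters(12, 500, planted, gc_rich_pwm, gc=0.4, seed=12)
        res = binding_site_null(promoters, gc_rich_pwm, n_batches=20, seed=0)
        assert res.observed_count == 12
        assert res.expected_count <= 2
        assert res.fdr is not None and res.fdr < 0.2

    def test_no_signal_fdr_near_one(self, gc_rich_pwm):
        # plant sites but evaluate with permissive thresholds so background
        # matches are common in both observed and shuffled sequences
        promoters = generate_promoters(10, 300, [], gc_rich_pwm, gc=0.6, seed=13)
        th = {"min_score": 0.3, "min_core_score": 0.0, "min_coverage": 0.0, "min_mean": 0.0}
        res = binding_site_null(promoters, gc_rich_pwm, n_batches=10, thresholds=th, seed=1)
        assert res.observed_count == 10
        assert res.fdr == pytest.approx(1.0)

    def test_zero_observed_fdr_undefined(self, gc_rich_pwm):
        promoters = generate_promoters(4, 300, [], gc_rich_pwm, gc=0.2, seed=14)
        res = binding_site_null(promoters, gc_rich_pwm, n_batches=5, seed=2)
        assert res.observed_count == 0
        assert res.fdr is None


class TestDnaseOverlap:
    def test_no_intervals_p_one(self, gc_rich_pwm):
        sites = [BindingSite("g0000", -10, "+", 1.0, 14)]
        promoters = generate_promoters(1, 500, [], gc_rich_pwm, seed=15)
        res = dnase_overlap_test(sites, [], promoters, n_rand=50, seed=0)
        assert res.n_genes_overlapping == 0
        assert res.p == 1.0

    def test_planted_overlap_significant(self, gc_rich_pwm):
        planted = [(i, -50, "+") for i in range(20)]
        promoters = generate_promoters(20, 2000, planted, gc_rich_pwm, gc=0.55, seed=16)
        dnase = generate_dnase_tracks(
            promoters, cover_planted=True, background_fraction=0.06, seed=17
        )
        sites = [
            BindingSite(p.gene, off, strand, 1.0, w)
            for p in promoters
            for off, strand, w in p.planted
        ]
        res = dnase_overlap_test(
            sites, dnase, promoters, gc_floor=0.5, n_rand=300, seed=18
        )
        assert res.n_genes_overlapping == 20
        assert res.p < 0.01

    def test_gene_without_gc_rich_stretch_excluded(self, gc_rich_pwm):
        promoters = generate_promoters(1, 300, [], gc_rich_pwm, gc=0.05, seed=19)
        sites = [BindingSite(promoters[0].gene, -10, "+", 1.0, 14)]
        dnase = [GenomicInterval(promoters[0].gene, 0, 300)]
        res = dnase_overlap_test(
            sites, dnase, promoters, gc_floor=0.99, n_rand=20, seed=20
        )
        assert promoters[0].gene in res.excluded_genes


class TestCompareScoreDistributions:
    def test_small_n_matches_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 8)))
            y = rng.normal(size=int(rng.integers(3, 8)))
            p = compare_score_distributions(x, y, alternative="two-sided")
            assert p == pytest.approx(wilcoxon_two_sided_exact(x, y), abs=1e-12)

    def test_shifted_foreground_detected(self):
        rng = np.random.default_rng(22)
        fg = rng.uniform(0, 1, 400) - 0.2
        bg = rng.uniform(0, 1, 1700)
        assert compare_score_distributions(fg, bg, alternative="less") < 0.05

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compare_score_distributions([], [1.0])


class TestGenomicInterval:
    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty interval"):
            GenomicInterval("g", 5, 5)

    def test_overlap_semantics(self):
        iv = GenomicInterval("g", 10, 20)
        assert iv.overlaps(19, 25)
        assert not iv.overlaps(20, 25)  # half-open
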