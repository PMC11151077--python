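"""Integration statistics: correlations, annotation geometry, activity, OLS."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cometh.dmr import DMR
from cometh.integrate import (
    ActivityRecord,
    DMRGenePair,
    GeneModel,
    UndefinedStatisticError,
    activity_score,
    assign_dmrs_to_genes,
    cgi_context,
    classify_pairs,
    correlation,
    filter_by_activity,
    gene_activity,
    interval_gap,
    merge_motifs,
    motif_occupancy,
    nearest_feature_distance,
    promoter_of,
    read_deg_table,
    signal_strength,
    variance_explained,
)


def _dmr(start, end, direction="hyper", chrom="chr1"):
    md = 0.2 if direction == "hyper" else -0.2
    return DMR(chrom, start, end, 5, md, 10.0, 0.01, 0.01, direction)


class TestCorrelation:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = correlation(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_spearman_hand_example(self):
        r, _ = correlation([1, 2, 3], [3, 1, 2], method="spearman")
        assert r == pytest.approx(-0.5, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlation([1, 2, 3], [5, 5, 5])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlation([1, 2], [3, 4])

    def test_nan_pairs_dropped(self):
        r1, _ = correlation([1, 2, 3, np.nan], [2, 4, 6, 1])
        r2, _ = correlation([1, 2, 3], [2, 4, 6])
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r_xy, _ = correlation(x, y)
        r_yx, _ = correlation(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        r_aff, _ = correlation(3.0 * x + 7.0, y)
        assert r_aff == pytest.approx(r_xy, abs=1e-12)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 5.0, size=25)
        y = rng.normal(size=25)
        r1, _ = correlation(x, y, method="spearman")
        r2, _ = correlation(np.exp(x), y, method="spearman")
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        r, p = correlation(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)


class TestSignalStrength:
    def test_zero_reads(self):
        assert signal_strength(0, 1000) == 0.0

    def test_worked_values(self):
        assert signal_strength(1000, 2000) == pytest.approx(
            math.log2(501), abs=1e-12
        )
        assert signal_strength(2, 1000) == pytest.approx(
            math.log2(3), abs=1e-12
        )

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            signal_strength(10, 0)
        with pytest.raises(ValueError):
            signal_strength(10, -5)


class TestPromoterAndAssignment:
    def test_symmetric_window(self):
        g = GeneModel("g1", "chr1", "+", 10_000, (9_000, 15_000))
        assert promoter_of(g) == (8_000, 12_000)

    def test_clipped_at_zero(self):
        g = GeneModel("g1", "chr1", "+", 500, (0, 3_000))
        assert promoter_of(g) == (0, 2_500)

    def test_strand_independent(self):
        plus = GeneModel("g1", "chr1", "+", 10_000, (9_000, 15_000))
        minus = GeneModel("g2", "chr1", "-", 10_000, (5_000, 10_001))
        assert promoter_of(plus) == promoter_of(minus)

    def test_dmr_inside_gene_body(self):
        genes = [GeneModel("g1", "chr1", "+", 1_000, (500, 5_000))]
        pairs = assign_dmrs_to_genes([_dmr(2_000, 2_100)], genes)
        assert pairs[0].gene_id == "g1"
        assert pairs[0].distance_bp == 0

    def test_within_threshold_assigned(self):
        genes = [GeneModel("g1", "chr1", "+", 1_000, (500, 5_000))]
        pairs = assign_dmrs_to_genes([_dmr(6_500, 6_600)], genes)
        assert pairs and pairs[0].distance_bp == 1_500

    def test_exactly_2kb_unassigned(self):
        # "less than 2 kb" is strict
        genes = [GeneModel("g1", "chr1", "+", 1_000, (500, 5_000))]
        assert assign_dmrs_to_genes([_dmr(7_000, 7_100)], genes) == []

    def test_nearest_gene_with_tie_break(self):
        genes = [
            GeneModel("gB", "chr1", "+", 1_000, (900, 2_000)),
            GeneModel("gA", "chr1", "+", 3_500, (3_100, 4_000)),
        ]
        # DMR equidistant (100 bp) from both spans
        pairs = assign_dmrs_to_genes([_dmr(2_100, 3_000)], genes)
        assert pairs[0].gene_id == "gA"

    def test_tss_anchor_variant(self):
        genes = [GeneModel("g1", "chr1", "+", 4_000, (500, 5_000))]
        span_pairs = assign_dmrs_to_genes([_dmr(600, 700)], genes)
        tss_pairs = assign_dmrs_to_genes([_dmr(600, 700)], genes,
                                         anchor="tss")
        assert span_pairs and span_pairs[0].distance_bp == 0
        assert tss_pairs == []  # 3.3 kb from the TSS point


class TestClassifyPairs:
    def _pair(self, direction):
        return DMRGenePair(_dmr(0, 100, direction), "g1", 0)

    def test_hyper_down(self):
        out = classify_pairs([self._pair("hyper")], {"g1": (-1.2, 0.001)})
        assert out[0].category == "Hyper-Down"

    def test_fdr_gate_gives_ns(self):
        out = classify_pairs([self._pair("hypo")], {"g1": (0.8, 0.2)})
        assert out[0].category == "NS"

    def test_hypo_up(self):
        out = classify_pairs([self._pair("hypo")], {"g1": (2.0, 1e-6)})
        assert out[0].category == "Hypo-Up"

    def test_absent_gene_is_ns(self):
        out = classify_pairs([self._pair("hyper")], {})
        assert out[0].category == "NS"

    def test_partition_exactly_one_category(self):
        rng = np.random.default_rng(11)
        cats = {"Hyper-Down", "Hyper-Up", "Hypo-Down", "Hypo-Up", "NS"}
        for _ in range(50):
            direction = rng.choice(["hyper", "hypo"])
            deg = {"g1": (float(rng.normal()), float(rng.uniform(0, 0.2)))}
            out = classify_pairs([self._pair(direction)], deg)
            assert out[0].category in cats


class TestCgiContext:
    CGIS = [(10_000, 11_000)]

    def test_inside(self):
        assert cgi_context(10_500, self.CGIS) == "CGI"

    def test_shore_boundary(self):
        assert cgi_context(11_000 + 1_999, self.CGIS) == "shore"
        assert cgi_context(11_000 + 2_000, self.CGIS) == "shelf"

    def test_shelf_upper_boundary(self):
        assert cgi_context(11_000 + 4_000, self.CGIS) == "shelf"
        assert cgi_context(11_000 + 4_001, self.CGIS) == "inteCGI"

    def test_far_away(self):
        assert cgi_context(50_000, self.CGIS) == "inteCGI"

    def test_no_cgis(self):
        assert cgi_context(100, []) == "inteCGI"


class TestIntervalUtilities:
    def test_overlap_distance_zero(self):
        assert nearest_feature_distance((100, 200), [(150, 300)]) == 0

    def test_adjacent_gap(self):
        assert nearest_feature_distance((100, 200), [(201, 300)]) == 1

    def test_empty_features_na(self):
        assert nearest_feature_distance((100, 200), []) is None

    def test_gap_symmetry(self):
        assert interval_gap((0, 10), (25, 30)) == interval_gap((25, 30), (0, 10))


class TestMergeMotifs:
    def test_nineteen_sites_three_clusters(self):
        # 19 overlapping sites laid out in 3 clusters
        motifs = (
            [(100 + 5 * i, 130 + 5 * i) for i in range(7)]
            + [(1_000 + 4 * i, 1_025 + 4 * i) for i in range(6)]
            + [(5_000 + 10 * i, 5_040 + 10 * i) for i in range(6)]
        )
        assert len(motifs) == 19
        assert len(merge_motifs(motifs)) == 3

    def test_disjoint_unchanged(self):
        motifs = [(0, 10), (20, 30), (40, 50)]
        assert merge_motifs(motifs) == motifs

    def test_nested_gives_outer(self):
        assert merge_motifs([(0, 100), (10, 20)]) == [(0, 100)]

    def test_disjoint_and_coverage_preserving(self):
        rng = np.random.default_rng(6)
        motifs = [
            (int(s), int(s + rng.integers(1, 50)))
            for s in rng.integers(0, 2_000, size=40)
        ]
        merged = merge_motifs(motifs)
        for a, b in zip(merged, merged[1:]):
            assert a[1] < b[0]
        covered = set()
        for s, e in motifs:
            covered.update(range(s, e))
        merged_cov = set()
        for s, e in merged:
            merged_cov.update(range(s, e))
        assert covered == merged_cov


class TestMotifOccupancy:
    def test_single_motif(self):
        # 100 bp DMR -> 500 bp extended; one 25 bp motif
        assert motif_occupancy((1_000, 1_100), [(1_020, 1_045)]) == pytest.approx(
            0.05, abs=1e-12
        )

    def test_no_motifs(self):
        assert motif_occupancy((1_000, 1_100), []) == 0.0

    def test_duplicate_motifs_count_twice(self):
        # two identical 250 bp motifs fully inside the 500 bp extended DMR
        dmr = (1_000, 1_100)
        motif = (950, 1_200)
        assert motif_occupancy(dmr, [motif, motif]) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_motif_clipped_to_extended_dmr(self):
        dmr = (1_000, 1_100)  # extended: [800, 1300)
        assert motif_occupancy(dmr, [(700, 900)]) == pytest.approx(
            100 / 500, abs=1e-12
        )


class TestActivityScore:
    def test_worked_arithmetic(self):
        assert activity_score(-0.5, 4.0) == pytest.approx(-1.0, abs=1e-12)

    def test_bad_fold_change(self):
        with pytest.raises(UndefinedStatisticError):
            activity_score(-0.5, 0.0)

    def test_gene_activity_drops_nonnegative_r(self):
        n = 10
        mask = [True] * 5 + [False] * 5
        expr = np.array([4.0, 4.2, 4.1, 4.3, 4.0, 2.0, 2.1, 2.0, 2.2, 2.1])
        meth_up = {"m1": expr + 0.01}  # positively correlated -> dropped
        assert gene_activity("g", meth_up, expr, mask) is None

    def test_gene_activity_averages_motifs(self):
        rng = np.random.default_rng(8)
        mask = np.array([True] * 6 + [False] * 6)
        expr = np.concatenate([rng.uniform(4, 5, 6), rng.uniform(1, 2, 6)])
        meth = {"m1": -expr, "m2": -2.0 * expr}
        rec = gene_activity("g", meth, expr, mask)
        assert rec is not None
        assert rec.motif_ids == ("m1", "m2")
        assert rec.activity < 0
        # both motifs perfectly anti-ranked: r = -1 each, so activity is
        # exactly -log2(fc) and sign(activity) = sign(r) * sign(log2fc)
        assert rec.r_spearman == pytest.approx(-1.0, abs=1e-9)
        assert rec.activity == pytest.approx(-rec.log2_fold_change, abs=1e-9)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match=">= 3"):
            gene_activity("g", {"m": [1, 2, 3, 4]}, [1, 2, 3, 4],
                          [True, True, False, False])

    def test_filter_threshold(self):
        recs = [
            ActivityRecord("a", ("m",), -0.5, 3.0, -1.5),
            ActivityRecord("b", ("m",), -0.5, 2.0, -1.0),
        ]
        kept = filter_by_activity(recs, threshold=1.2)
        assert [r.gene_id for r in kept] == ["a"]


class TestVarianceExplained:
    def test_noise_free_interaction_recovery(self):
        rng = np.random.default_rng(10)
        meth = rng.uniform(0, 1, 30)
        tf = rng.normal(2, 1, 30)
        y = 1.0 + 2.0 * meth - 0.5 * tf + 1.5 * meth * tf
        model = variance_explained(y, meth, tf)
        assert model.adj_r2_interaction == pytest.approx(1.0, abs=1e-10)

    def test_independent_predictors_near_zero(self):
        rng = np.random.default_rng(20)
        n = 4_000
        y = rng.normal(size=n)
        model = variance_explained(y, rng.uniform(size=n), rng.normal(size=n))
        for v in (model.adj_r2_meth, model.adj_r2_tf, model.adj_r2_joint,
                  model.adj_r2_interaction):
            assert abs(v) < 0.01

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(30)
        meth = rng.uniform(0, 1, 10)
        tf = rng.normal(size=10)
        y = 0.5 + meth - 2 * tf + rng.normal(0, 0.1, 10)
        model = variance_explained(y, meth, tf)
        # closed-form normal equations for the joint model
        X = np.column_stack([np.ones(10), meth, tf])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        adj = 1 - (1 - r2) * 9 / (10 - 2 - 1)
        assert model.adj_r2_joint == pytest.approx(adj, abs=1e-10)

    def test_raw_r2_monotone_over_nested_models(self):
        rng = np.random.default_rng(40)
        meth = rng.uniform(0, 1, 50)
        tf = rng.normal(size=50)
        y = meth + 0.5 * tf + rng.normal(0, 0.5, 50)
        raw = variance_explained(y, meth, tf).raw_r2
        assert raw[0] <= raw[2] + 1e-12
        assert raw[1] <= raw[2] + 1e-12
        assert raw[2] <= raw[3] + 1e-12

    def test_collinear_design_rejected(self):
        meth = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        with pytest.raises(ValueError, match="collinear"):
            variance_explained(meth * 2, meth, meth)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="> 4"):
            variance_explained([1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1])


class TestReadDegTable:
    def test_valid_table(self):
        import pandas as pd

        df = pd.DataFrame(
            {"gene_id": ["g1"], "log2FC": [1.5], "FDR": [0.01]}
        )
        assert read_deg_table(df) == {"g1": (1.5, 0.01)}

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            read_deg_table(pd.DataFrame({"gene_id": ["g1"]}))
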