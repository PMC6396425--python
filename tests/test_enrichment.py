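"""eQTL/GO enrichment: 2x2 machinery, BH, SNP-to-gene strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from ldhic.enrichment import (GeneAnnotation, GOAnnotation, bh_adjust,
                              fisher_exact_2x2, go_enrichment_compare,
                              interaction_feature_vectors,
                              quantile_distance_bins, snp_to_genes,
                              stratified_or)
from ldhic.interactions import InteractionSet
from ldhic.ld import LDBlock, LDPairTable


def annotation(rows):
    return GeneAnnotation(pd.DataFrame(rows, columns=[
        "gene_id", "tss", "promoter_start", "promoter_end",
        "bait_start", "bait_end"]))


def inter(rows):
    return InteractionSet(pd.DataFrame([
        {"chrom": "chr1", "start1": s1, "end1": e1, "start2": s2,
         "end2": e2, "score": sc, "kind": "pchic"}
        for s1, e1, s2, e2, sc in rows]))


def empty_pairs():
    return LDPairTable(pd.DataFrame(
        columns=["pos_i", "pos_j", "r2", "dprime", "distance"]))


class TestFeatureVectors:
    @pytest.fixture
    def ann(self):
        return annotation([
            ("GA", 1500, 1000, 2000, 1000, 3000),
            ("GB", 51_500, 51_000, 52_000, 51_000, 53_000),
        ])

    def test_eqtl_in_pir_targeting_bait(self, ann):
        calls = inter([(1000, 3000, 20_000, 22_000, 9.0)])
        eqtls = pd.DataFrame({"snp_pos": [21_000], "gene_id": ["GA"]})
        f = interaction_feature_vectors(calls, eqtls, ann, empty_pairs(),
                                        np.array([], dtype=int))
        assert bool(f["has_eqtl"].iloc[0])

    def test_eqtl_in_bait_not_pir_excluded(self, ann):
        calls = inter([(1000, 3000, 20_000, 22_000, 9.0)])
        eqtls = pd.DataFrame({"snp_pos": [2000], "gene_id": ["GA"]})
        f = interaction_feature_vectors(calls, eqtls, ann, empty_pairs(),
                                        np.array([], dtype=int))
        assert not bool(f["has_eqtl"].iloc[0])

    def test_eqtl_targeting_other_bait_excluded(self, ann):
        calls = inter([(1000, 3000, 20_000, 22_000, 9.0)])
        eqtls = pd.DataFrame({"snp_pos": [21_000], "gene_id": ["GB"]})
        f = interaction_feature_vectors(calls, eqtls, ann, empty_pairs(),
                                        np.array([], dtype=int))
        assert not bool(f["has_eqtl"].iloc[0])

    def test_unknown_target_gene_rejected(self, ann):
        calls = inter([(1000, 3000, 20_000, 22_000, 9.0)])
        eqtls = pd.DataFrame({"snp_pos": [21_000], "gene_id": ["GZ"]})
        with pytest.raises(ValueError, match="GZ"):
            interaction_feature_vectors(calls, eqtls, ann, empty_pairs(),
                                        np.array([], dtype=int))

    def test_closest_gene_and_strong_ld_flags(self, ann):
        calls = inter([(1000, 3000, 4000, 6000, 9.0)])
        eqtls = pd.DataFrame({"snp_pos": [], "gene_id": []})
        snps = np.array([1500, 4500])
        pairs = LDPairTable(pd.DataFrame({
            "pos_i": [1500], "pos_j": [4500], "r2": [0.9],
            "dprime": [1.0], "distance": [3000]}))
        f = interaction_feature_vectors(calls, eqtls, ann, pairs, snps)
        assert bool(f["closest_gene_in_bait"].iloc[0])  # GA promoter nearest
        assert bool(f["strong_ld"].iloc[0])


class TestQuantileBins:
    def test_uniform_distances_balanced(self, rng):
        rows = [(int(s), int(s) + 1000, int(s) + d, int(s) + d + 1000, 9.0)
                for s, d in zip(rng.integers(0, 10 ** 6, size=200),
                                rng.integers(2000, 1_000_000, size=200))]
        labels, keep = quantile_distance_bins(inter(rows), n_bins=4)
        counts = np.bincount(labels)
        assert counts.max() - counts.min() <= 2

    def test_beyond_max_dist_dropped(self, rng):
        rows = [(0, 1000, 3_000_000, 3_001_000, 9.0)] + [
            (int(s), int(s) + 1000, int(s) + 50_000 + 100 * k,
             int(s) + 51_000 + 100 * k, 9.0)
            for k, s in enumerate(rng.integers(0, 10 ** 6, size=30))]
        labels, keep = quantile_distance_bins(inter(rows), n_bins=3)
        assert keep.sum() == 30 and not keep[0]

    def test_tied_distances_rejected(self):
        rows = [(k * 10_000, k * 10_000 + 1000, k * 10_000 + 5000,
                 k * 10_000 + 6000, 9.0) for k in range(20)]
        with pytest.raises(ValueError):
            quantile_distance_bins(inter(rows), n_bins=4)

    def test_fewer_than_bins_rejected(self):
        rows = [(0, 1000, 5000, 6000, 9.0)]
        with pytest.raises(ValueError):
            quantile_distance_bins(inter(rows), n_bins=4)


def _wald_oracle(a, b, c, d):
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    lo = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return np.exp(lo), np.exp(lo - 1.96 * se), np.exp(lo + 1.96 * se)


def _irls_logistic(y, x, n_iter=50):
    """Reference one-covariate logistic fit by IRLS (test oracle)."""
    X = np.column_stack([np.ones(len(x)), x.astype(float)])
    beta = np.zeros(2)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, X.T @ (w * z))
    return beta[1]


class TestStratifiedOR:
    def test_balanced_table_or_one(self):
        y = np.array([1] * 10 + [0] * 10 + [1] * 10 + [0] * 10, dtype=bool)
        x = np.array([1] * 20 + [0] * 20, dtype=bool)
        res = stratified_or(y, x, np.zeros(40))
        assert res[0].or_estimate == pytest.approx(1.0)
        assert res[0].p == pytest.approx(1.0)

    def test_textbook_table(self):
        """(a,b,c,d)=(90,10,50,50): OR = ad/bc = 9, Wald CI per the
        standard formula."""
        y = np.concatenate([np.ones(90), np.zeros(10),
                            np.ones(50), np.zeros(50)]).astype(bool)
        x = np.concatenate([np.ones(100), np.zeros(100)]).astype(bool)
        res = stratified_or(y, x, np.zeros(200))[0]
        assert res.or_estimate == pytest.approx(9.0)
        e_or, e_lo, e_hi = _wald_oracle(90, 10, 50, 50)
        assert res.ci_low == pytest.approx(e_lo, rel=1e-4)
        assert res.ci_high == pytest.approx(e_hi, rel=1e-4)

    def test_equals_logistic_regression(self, rng):
        """With one binary covariate the 2x2 log OR equals the
        logistic-regression coefficient."""
        x = rng.random(500) < 0.4
        p = np.where(x, 0.55, 0.3)
        y = rng.random(500) < p
        res = stratified_or(y, x, np.zeros(500))[0]
        assert res.log_or == pytest.approx(_irls_logistic(y, x), abs=1e-6)

    def test_single_class_stratum_flagged(self):
        y = np.array([True, False, True])
        x = np.array([True, True, True])
        res = stratified_or(y, x, np.zeros(3))
        assert res[0].note != ""
        assert np.isnan(res[0].or_estimate)

    def test_haldane_correction_on_zero_cell(self):
        y = np.array([1] * 10 + [0] * 0 + [1] * 5 + [0] * 5, dtype=bool)
        x = np.array([1] * 10 + [0] * 10, dtype=bool)
        res = stratified_or(y, x, np.zeros(20))[0]
        expect = (10.5 * 5.5) / (0.5 * 5.5)
        assert res.or_estimate == pytest.approx(expect)


def _fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by enumerating every table with the
    observed margins (test oracle)."""
    r1, r2 = a + b, c + d
    c1 = a + c

    def logp(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        return (gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1)
                + gammaln(b + d + 1) - gammaln(a + b + c + d + 1)
                - gammaln(aa + 1) - gammaln(bb + 1) - gammaln(cc + 1)
                - gammaln(dd + 1))
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = np.exp([logp(aa) for aa in range(lo, hi + 1)])
    obs = np.exp(logp(a))
    return float(probs[probs <= obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_modal_table_p_one(self):
        _, p = fisher_exact_2x2(10, 10, 10, 10)
        assert p == pytest.approx(1.0)

    def test_strong_table_matches_enumeration(self):
        or_est, p = fisher_exact_2x2(20, 5, 5, 20)
        assert or_est == pytest.approx(16.0)
        assert p == pytest.approx(_fisher_enumeration(20, 5, 5, 20),
                                  rel=1e-9)

    @pytest.mark.parametrize("table", [
        (3, 7, 12, 2), (1, 9, 8, 6), (15, 2, 3, 11), (5, 5, 6, 4),
    ])
    def test_matches_enumeration_on_small_margins(self, table):
        _, p = fisher_exact_2x2(*table)
        assert p == pytest.approx(_fisher_enumeration(*table), rel=1e-9)

    def test_transpose_symmetry(self):
        _, p1 = fisher_exact_2x2(8, 3, 5, 12)
        _, p2 = fisher_exact_2x2(8, 5, 3, 12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 5, 5)


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_dominates_p(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_uniform_null_few_discoveries(self, rng):
        q = bh_adjust(rng.random(10_000))
        assert np.mean(q < 0.05) < 0.001


class TestSnpToGenes:
    @pytest.fixture
    def ann(self):
        return annotation([
            ("GA", 10_500, 10_000, 11_000, 10_000, 12_000),
            ("GB", 50_500, 50_000, 51_000, 50_000, 52_000),
            ("GC", 90_500, 90_000, 91_000, np.nan, np.nan),
        ])

    def test_snp_inside_promoter_is_closest(self, ann):
        out = snp_to_genes(np.array([10_400]), "closest", ann)
        assert out == [{"GA"}]

    def test_snp_outside_blocks_empty(self, ann):
        blocks = [LDBlock("chr1", 40_000, 60_000, 5)]
        out = snp_to_genes(np.array([10_400]), "ld_block", ann,
                           blocks=blocks)
        assert out == [set()]

    def test_ld_block_collects_overlapping_promoters(self, ann):
        blocks = [LDBlock("chr1", 9000, 95_000, 5)]
        out = snp_to_genes(np.array([30_000]), "ld_block", ann,
                           blocks=blocks)
        assert out == [{"GA", "GB", "GC"}]

    def test_pchic_bait_genes(self, ann):
        calls = inter([(10_000, 12_000, 200_000, 205_000, 9.0),
                       (50_000, 52_000, 200_000, 205_000, 2.0)])
        out = snp_to_genes(np.array([201_000]), "pchic", ann,
                           interactions=calls)
        assert out == [{"GA"}]  # only the significant interaction counts

    def test_missing_auxiliary_rejected(self, ann):
        with pytest.raises(ValueError):
            snp_to_genes(np.array([1]), "ld_block", ann)
        with pytest.raises(ValueError):
            snp_to_genes(np.array([1]), "pchic", ann)

    def test_all_strategies_match_brute_force(self, rng, ann):
        snps = rng.integers(1, 250_000, size=30)
        blocks = [LDBlock("chr1", 5000, 55_000, 5),
                  LDBlock("chr1", 80_000, 100_000, 5)]
        calls = inter([(10_000, 12_000, 150_000, 160_000, 9.0),
                       (50_000, 52_000, 180_000, 190_000, 9.0)])
        closest = snp_to_genes(snps, "closest", ann)
        ld = snp_to_genes(snps, "ld_block", ann, blocks=blocks)
        pc = snp_to_genes(snps, "pchic", ann, interactions=calls)
        proms = {"GA": (10_000, 11_000), "GB": (50_000, 51_000),
                 "GC": (90_000, 91_000)}
        for k, p in enumerate(snps):
            dists = {g: max(s - (p - 1), (p - 1) - (e - 1), 0)
                     for g, (s, e) in proms.items()}
            dmin = min(dists.values())
            assert closest[k] == {min(g for g, v in dists.items()
                                      if v == dmin)}
            expect_ld = set()
            for b in blocks:
                if b.start <= p <= b.end:
                    for g, (s, e) in proms.items():
                        if s < b.end and e > b.start - 1:
                            expect_ld.add(g)
            assert ld[k] == expect_ld
            expect_pc = set()
            for r, g in ((calls.df.iloc[0], "GA"), (calls.df.iloc[1], "GB")):
                if r["start2"] < p <= r["end2"]:
                    expect_pc.add(g)
            assert pc[k] == expect_pc


class TestGOCompare:
    def test_planted_term_detected_and_null_clean(self, rng):
        from ldhic.experiments import go_detection_sweep
        df = go_detection_sweep(n_seeds=3, base_seed=77)
        assert (df["q_planted"] < 0.05).all()
        assert (df["n_null_discoveries"] == 0).all()

    def test_phenotype_without_mapped_genes(self):
        ann = annotation([("GA", 1500, 1000, 2000, 1000, 3000)] * 1)
        go = GOAnnotation({"GA": {"GO:1"}})
        calls = inter([(1000, 3000, 9000, 11_000, 9.0)])
        res, counts = go_enrichment_compare(
            {"phen": np.array([500_000])}, ann, go, interactions=calls,
            strategies=("pchic",))
        assert res["note"].iloc[0] == "no mapped units"

    def test_go_annotation_drops_empty_sets(self):
        go = GOAnnotation({"GA": {"GO:1"}, "GB": set()})
        assert len(go) == 1
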