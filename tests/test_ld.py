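"""Unit and property tests for pairwise LD and block calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldhic.ld import (HaplotypePanel, LDBlock, TwoLocusCounts, call_ld_blocks,
                      dprime_ci, em_haplotype_freqs, pairwise_ld_scan,
                      r2_dprime, two_locus_counts)

from conftest import brute_force_r2_dprime


class TestTwoLocusCounts:
    def test_perfect_coupling_tally(self):
        panel = HaplotypePanel(np.array([[1, 1], [1, 1], [0, 0], [0, 0]]),
                               np.array([10, 20]))
        c = two_locus_counts(panel, 0, 1)
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (2, 0, 0, 2)

    def test_repulsion_tally(self):
        panel = HaplotypePanel(np.tile([1, 0], (4, 1)), np.array([10, 20]))
        c = two_locus_counts(panel, 0, 1)
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (0, 4, 0, 0)

    def test_matches_exhaustive_tally(self, random_panel, rng):
        for _ in range(20):
            i, j = rng.choice(random_panel.n_snps, size=2, replace=False)
            c = two_locus_counts(random_panel, i, j)
            a = random_panel.alleles[:, i]
            b = random_panel.alleles[:, j]
            assert c.n_AB == np.sum((a == 1) & (b == 1))
            assert c.n_ab == np.sum((a == 0) & (b == 0))
            assert c.total == random_panel.n_haplotypes

    def test_index_errors(self, random_panel):
        with pytest.raises(ValueError):
            two_locus_counts(random_panel, 3, 3)
        with pytest.raises(IndexError):
            two_locus_counts(random_panel, 0, random_panel.n_snps)


class TestR2Dprime:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 0, 0, 50), (1.0, 1.0)),
        ((25, 25, 25, 25), (0.0, 0.0)),
        ((40, 10, 10, 40), (0.36, 0.6)),
    ])
    def test_closed_forms(self, counts, expected):
        r2, dp = r2_dprime(TwoLocusCounts(*counts))
        assert r2 == pytest.approx(expected[0], abs=1e-12)
        assert dp == pytest.approx(expected[1], abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            r2_dprime(TwoLocusCounts(10, 10, 0, 0))

    @given(st.tuples(*[st.integers(1, 60)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariants(self, quad):
        """0 <= r² <= D′ <= 1; symmetric in locus order; allele-label swap
        at one locus preserves both statistics."""
        c = TwoLocusCounts(*quad)
        r2, dp = r2_dprime(c)
        assert 0.0 <= r2 <= dp <= 1.0
        # locus swap: (AB, aB, Ab, ab)
        r2_s, dp_s = r2_dprime(TwoLocusCounts(c.n_AB, c.n_aB, c.n_Ab, c.n_ab))
        assert r2_s == pytest.approx(r2, abs=1e-12)
        assert dp_s == pytest.approx(dp, abs=1e-12)
        # allele-label swap at locus A: (aB, ab, AB, Ab)
        r2_f, dp_f = r2_dprime(TwoLocusCounts(c.n_aB, c.n_ab, c.n_AB, c.n_Ab))
        assert r2_f == pytest.approx(r2, abs=1e-12)
        assert dp_f == pytest.approx(dp, abs=1e-12)

    def test_matches_brute_force(self, random_panel, rng):
        for _ in range(20):
            i, j = rng.choice(random_panel.n_snps, size=2, replace=False)
            r2, dp = r2_dprime(two_locus_counts(random_panel, i, j))
            e_r2, e_dp = brute_force_r2_dprime(random_panel.alleles[:, i],
                                               random_panel.alleles[:, j])
            assert r2 == pytest.approx(e_r2, abs=1e-12)
            assert dp == pytest.approx(e_dp, abs=1e-12)


def _em_grid_oracle(table, step=1e-4):
    """Maximize the multinomial likelihood over a D grid (test oracle)."""
    g = np.asarray(table, dtype=float)
    n_hap = 2 * g.sum()
    # allele counts are fixed by the margins
    pA = (2 * g[2].sum() + g[1].sum()) / n_hap
    pB = (2 * g[:, 2].sum() + g[:, 1].sum()) / n_hap
    d_lo = max(-pA * pB, -(1 - pA) * (1 - pB))
    d_hi = min(pA * (1 - pB), (1 - pA) * pB)
    best, best_ll = None, -np.inf
    for d in np.arange(d_lo, d_hi + step, step):
        p = np.array([pA * pB + d, pA * (1 - pB) - d,
                      (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d])
        if (p < -1e-12).any():
            continue
        p = np.clip(p, 1e-300, 1.0)
        # genotype-cell likelihood under random mating
        ll = 0.0
        hap = {(1, 1): p[0], (1, 0): p[1], (0, 1): p[2], (0, 0): p[3]}
        for ga in range(3):
            for gb in range(3):
                if g[ga, gb] == 0:
                    continue
                prob = 0.0
                for a1 in (0, 1):
                    for b1 in (0, 1):
                        a2, b2 = ga - a1, gb - b1
                        if a2 in (0, 1) and b2 in (0, 1):
                            prob += hap[(a1, b1)] * hap[(a2, b2)]
                ll += g[ga, gb] * np.log(max(prob, 1e-300))
        if ll > best_ll:
            best_ll, best = ll, p
    return best


class TestEMHaplotypeFreqs:
    def test_no_double_het_closed_form(self):
        table = np.zeros((3, 3))
        table[2, 2] = 5  # AABB
        table[0, 0] = 3  # aabb
        table[2, 1] = 2  # AABb
        freqs, it = em_haplotype_freqs(table)
        assert it == 1
        base = np.array([12, 2, 0, 6], dtype=float)
        np.testing.assert_allclose(freqs, base / base.sum(), atol=1e-12)

    def test_symmetric_fixed_point(self):
        table = np.zeros((3, 3))
        table[1, 1] = 10
        freqs, _ = em_haplotype_freqs(table)
        np.testing.assert_allclose(freqs, 0.25, atol=1e-9)

    def test_matches_likelihood_grid(self):
        table = np.array([[10, 4, 1], [5, 12, 4], [2, 5, 7]], dtype=float)
        freqs, _ = em_haplotype_freqs(table, tol=1e-12)
        oracle = _em_grid_oracle(table)
        np.testing.assert_allclose(freqs, oracle, atol=1e-3)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonconvergence_carries_estimate(self):
        table = np.array([[10, 4, 1], [5, 12, 4], [2, 5, 7]], dtype=float)
        with pytest.raises(RuntimeError) as exc:
            em_haplotype_freqs(table, tol=0.0, max_iter=3)
        assert hasattr(exc.value, "last_estimate")


class TestDprimeCI:
    def test_concentrated_at_one(self):
        lo, hi = dprime_ci(TwoLocusCounts(500, 0, 0, 500))
        assert lo >= 0.98
        assert hi == 1.0

    def test_equilibrium_covers_small_values(self):
        lo, hi = dprime_ci(TwoLocusCounts(25, 25, 25, 25))
        assert lo <= 0.2

    def test_more_data_never_widens(self):
        widths = []
        for mult in (1, 2, 4, 8):
            lo, hi = dprime_ci(TwoLocusCounts(30 * mult, 10 * mult,
                                              10 * mult, 30 * mult))
            widths.append(hi - lo)
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(widths, widths[1:]))

    def test_matches_direct_grid_evaluation(self):
        """CI bounds equal a direct normalized-likelihood evaluation."""
        c = TwoLocusCounts(70, 20, 15, 95)
        grid = np.arange(0, 1.0005, 0.001)
        n = np.array([70, 20, 15, 95], dtype=float)
        tot = n.sum()
        pA = (n[0] + n[1]) / tot
        pB = (n[0] + n[2]) / tot
        d_hat = n[0] / tot - pA * pB
        dmax = (min(pA * (1 - pB), (1 - pA) * pB) if d_hat >= 0
                else min(pA * pB, (1 - pA) * (1 - pB)))
        sign = 1.0 if d_hat >= 0 else -1.0
        lls = []
        for g in grid:
            d = sign * dmax * g
            p = np.clip([pA * pB + d, pA * (1 - pB) - d,
                         (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d], 0, 1)
            with np.errstate(divide="ignore"):
                terms = n * np.log(p)
            lls.append(np.sum(np.where(n == 0, 0.0, terms)))
        w = np.exp(np.array(lls) - max(lls))
        w /= w.sum()
        cum = np.cumsum(w)
        exp_lo = grid[np.argmax(cum >= 0.05)]
        upper = 1 - cum + w
        exp_hi = grid[len(grid) - 1 - np.argmax(upper[::-1] >= 0.05)]
        lo, hi = dprime_ci(c)
        assert lo == pytest.approx(exp_lo, abs=1e-12)
        assert hi == pytest.approx(exp_hi, abs=1e-12)


class TestPairwiseScan:
    def test_matches_quadratic_oracle(self, random_panel):
        table = pairwise_ld_scan(random_panel, maf_min=0.05,
                                 max_dist=2_000_000, r2_floor=0.01)
        maf = random_panel.maf
        keep = np.flatnonzero(maf >= 0.05)
        expected = {}
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                i, j = keep[a], keep[b]
                r2, dp = brute_force_r2_dprime(random_panel.alleles[:, i],
                                               random_panel.alleles[:, j])
                if r2 >= 0.01:
                    expected[(random_panel.positions[i],
                              random_panel.positions[j])] = (r2, dp)
        got = {(r.pos_i, r.pos_j): (r.r2, r.dprime)
               for r in table.df.itertuples()}
        assert set(got) == set(expected)
        for k in expected:
            assert got[k][0] == pytest.approx(expected[k][0], abs=1e-9)
            assert got[k][1] == pytest.approx(expected[k][1], abs=1e-9)

    def test_max_dist_window(self):
        alleles = np.array([[1, 1], [1, 1], [0, 0], [0, 1]] * 10,
                           dtype=np.uint8)
        panel = HaplotypePanel(alleles, np.array([1, 2_000_002]))
        table = pairwise_ld_scan(panel)
        assert len(table) == 0
        panel2 = HaplotypePanel(alleles, np.array([1, 2_000_001]))
        assert len(pairwise_ld_scan(panel2)) == 1

    def test_floor_omits_weak_pairs(self, rng):
        # two nearly independent SNPs: r² below 1% omitted
        a = (rng.random(4000) < 0.5).astype(np.uint8)
        b = (rng.random(4000) < 0.5).astype(np.uint8)
        panel = HaplotypePanel(np.column_stack([a, b]), np.array([100, 200]))
        table = pairwise_ld_scan(panel)
        from conftest import brute_force_r2_dprime as bf
        r2, _ = bf(a, b)
        assert (len(table) == 0) == (r2 < 0.01)


def _two_segment_panel(n_hap=600, seed=5):
    """Two 3-SNP perfect-LD segments separated by a deterministic
    recombination break."""
    rng = np.random.default_rng(seed)
    left = rng.integers(0, 2, size=n_hap).astype(np.uint8)
    right = rng.integers(0, 2, size=n_hap).astype(np.uint8)
    alleles = np.column_stack([left, left, left, right, right, right])
    positions = np.array([1000, 2000, 3000, 50_000, 51_000, 52_000])
    return HaplotypePanel(alleles, positions)


class TestBlockCalling:
    def test_two_perfect_segments_give_two_blocks(self):
        panel = _two_segment_panel()
        blocks = call_ld_blocks(panel)
        assert len(blocks) == 2
        assert (blocks[0].start, blocks[0].end) == (1000, 3000)
        assert (blocks[1].start, blocks[1].end) == (50_000, 52_000)
        assert blocks[0].snp_count == blocks[1].snp_count == 3

    def test_independent_snps_give_no_blocks(self, rng):
        alleles = (rng.random((2000, 12)) < 0.5).astype(np.uint8)
        panel = HaplotypePanel(
            alleles, np.arange(1, 13) * 1000)
        assert call_ld_blocks(panel) == []

    def test_span_cap_rejects_wide_candidates(self):
        rng = np.random.default_rng(7)
        hap = rng.integers(0, 2, size=800).astype(np.uint8)
        alleles = np.column_stack([hap, hap, hap])
        panel = HaplotypePanel(alleles, np.array([1, 1_000_000, 2_000_002]))
        blocks = call_ld_blocks(panel)
        # full candidate spans 2,000,001 bp -> rejected; sub-candidate kept
        assert all(b.span <= 2_000_000 for b in blocks)
        assert any(b.snp_count == 2 for b in blocks)

    def test_blocks_non_overlapping_and_sorted(self):
        panel = _two_segment_panel()
        blocks = call_ld_blocks(panel)
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.end < b2.start
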