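"""Intergenic distances, antisense fractions, permutation nulls, rank tests."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from termsig.annotation import GenomeAnnotation, GenomicInterval, GenePairing
from termsig.context import (
    PermutationConfig,
    compute_quantity,
    f_as,
    igr,
    igr_term,
    ks_set_vs_null,
    permutation_median_test,
    ranksum_compare,
    wilcoxon_departure_from_zero,
)
from termsig.simulate import SimulationConfig, simulate_annotation

from conftest import make_gene


# ---------------------------------------------------------------------------
# distances and antisense fraction


class TestIgr:
    def pair(self, gap):
        # partner 3'UTR ends at 1000 (1-based), focal 5'UTR starts 1000+gap+1
        partner = make_gene("p", "chr1", "+", 600, 50, 250, 100)  # utr3 end 1000
        focal_start = 1000 + gap
        focal = make_gene("f", "chr1", "+", focal_start, 50, 300, 50)
        ann = GenomeAnnotation([partner, focal], {"chr1": 10000})
        pairing = GenePairing("f", "p", "upstream_same_strand", 0)
        return ann, pairing

    def test_fifty_bp_gap(self):
        ann, pairing = self.pair(50)
        assert igr(ann, pairing) == 50

    def test_abutting_is_zero(self):
        ann, pairing = self.pair(0)
        assert igr(ann, pairing) == 0

    def test_overlap_is_negative(self):
        ann, pairing = self.pair(-50)
        assert igr(ann, pairing) == -50

    def test_minus_strand_orientation(self):
        # minus-strand pair: partner lies to the right of the focal gene
        focal = make_gene("f", "chr1", "-", 1000, 50, 300, 50)   # utr5 end 1400
        partner = make_gene("p", "chr1", "-", 1475, 50, 250, 75)  # utr3 1475-1550
        ann = GenomeAnnotation([focal, partner], {"chr1": 10000})
        pairing = GenePairing("f", "p", "upstream_same_strand", 0)
        assert igr(ann, pairing) == 75

    def test_wrong_relation_rejected(self):
        ann, _ = self.pair(50)
        with pytest.raises(ValueError):
            igr(ann, GenePairing("f", "p", "downstream_reverse", 0))


class TestIgrTerm:
    def build(self, partner_start):
        focal = make_gene("f", "chr1", "+", 0, 100, 800, 100)  # span 0-1000
        partner = make_gene("p", "chr1", "-", partner_start, 100, 700, 100)
        ann = GenomeAnnotation([focal, partner], {"chr1": 10000})
        return ann, GenePairing("f", "p", "downstream_reverse", 0)

    def test_gap_between_convergent_genes(self):
        ann, pairing = self.build(1100)
        assert igr_term(ann, pairing) == 100

    def test_overlapping_convergent_genes_negative(self):
        ann, pairing = self.build(900)
        assert igr_term(ann, pairing) == -100

    def test_same_strand_pairing_rejected(self):
        focal = make_gene("f", "chr1", "+", 0, 100, 800, 100)
        partner = make_gene("p", "chr1", "+", 1100, 100, 700, 100)
        ann = GenomeAnnotation([focal, partner], {"chr1": 10000})
        with pytest.raises(ValueError):
            igr_term(ann, GenePairing("f", "p", "downstream_reverse", 0))

    def test_invariant_under_reverse_complement(self):
        cfg = SimulationConfig(seed=3, n_genes=60, short_igr_set_size=6,
                               n_readthrough=6, n_de_down=3, n_de_up=3)
        ann, _ = simulate_annotation(cfg)
        L = ann.chrom_lengths

        def rc_iv(iv, flip):
            return GenomicInterval(iv.chrom, L[iv.chrom] - iv.end,
                                   L[iv.chrom] - iv.start, flip)

        rc_genes = []
        for g in ann:
            flip = "-" if g.strand == "+" else "+"
            rc_genes.append(
                type(g)(gene_id=g.gene_id, biotype=g.biotype, strand=flip,
                        orf=rc_iv(g.orf, flip),
                        utr5=None if g.utr5 is None else rc_iv(g.utr5, flip),
                        utr3=None if g.utr3 is None else rc_iv(g.utr3, flip))
            )
        rc = GenomeAnnotation(rc_genes, L)
        for quantity in ("igr", "igr_term"):
            a = compute_quantity(ann, quantity)
            b = compute_quantity(rc, quantity)
            pd.testing.assert_series_equal(a, b, check_names=False)


class TestFas:
    def test_no_antisense_is_zero(self):
        ann = GenomeAnnotation(
            [make_gene("g", "chr1", "+", 1000, 0, 1000, 0)], {"chr1": 10000}
        )
        assert f_as(ann, "g") == 0.0

    def test_fully_covered_is_one(self):
        ann = GenomeAnnotation(
            [make_gene("g", "chr1", "+", 1000, 0, 1000, 0),
             make_gene("as", "chr1", "-", 900, 0, 1300, 0)],
            {"chr1": 10000},
        )
        assert f_as(ann, "g") == 1.0

    def test_half_covered(self):
        # antisense covering 1501-2000 of a 1001-2000 (1-based) gene
        ann = GenomeAnnotation(
            [make_gene("g", "chr1", "+", 1000, 0, 1000, 0),
             make_gene("as", "chr1", "-", 1500, 0, 800, 0)],
            {"chr1": 10000},
        )
        assert f_as(ann, "g") == 0.5


# ---------------------------------------------------------------------------
# permutation null of the median


def universe(values):
    return pd.Series({f"g{i}": v for i, v in enumerate(values)}, dtype=float)


class TestPermutationMedianTest:
    def test_exhaustive_hand_enumerated_example(self):
        u = universe([1, 2, 3, 4])
        cfg = PermutationConfig(n_random_sets=1, set_size=2, mode="exhaustive")
        res = permutation_median_test(u, ["g0", "g1"], cfg)
        assert sorted(res.null_stats) == [1.5, 2.0, 2.5, 2.5, 3.0, 3.5]
        assert res.observed_stat == 1.5
        assert res.k_le == 1
        assert res.p_le == pytest.approx(1 / 6)

    def test_degenerate_whole_universe_set(self):
        u = universe([5, 7, 9])
        cfg = PermutationConfig(n_random_sets=50, set_size=3, seed=0)
        res = permutation_median_test(u, list(u.index), cfg)
        assert np.all(res.null_stats == res.observed_stat)
        assert res.p_le == res.p_ge == 1.0

    def test_zero_exceedance_reported_as_bound(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.full(20, 10.0), rng.normal(500, 50, 280)])
        u = universe(vals)
        observed = [f"g{i}" for i in range(20)]  # the 20 short values
        cfg = PermutationConfig(n_random_sets=10_000, set_size=20, seed=1)
        res = permutation_median_test(u, observed, cfg)
        assert res.k_le == 0
        assert res.p_report == "< 1/10,000"
        assert res.p_le == pytest.approx(1 / 10_001)

    def test_same_seed_bit_identical_null(self):
        u = universe(np.arange(30))
        cfg = PermutationConfig(n_random_sets=500, set_size=5, seed=7)
        a = permutation_median_test(u, ["g0", "g1", "g2", "g3", "g4"], cfg)
        b = permutation_median_test(u, ["g0", "g1", "g2", "g3", "g4"], cfg)
        np.testing.assert_array_equal(a.null_stats, b.null_stats)

    def test_set_size_larger_than_universe_rejected(self):
        u = universe([1, 2, 3])
        cfg = PermutationConfig(n_random_sets=10, set_size=4)
        with pytest.raises(ValueError):
            permutation_median_test(u, ["g0"], cfg)

    def test_observed_gene_missing_from_universe_rejected(self):
        u = universe([1, 2, 3])
        cfg = PermutationConfig(n_random_sets=10, set_size=1, seed=0)
        with pytest.raises(ValueError):
            permutation_median_test(u, ["nope"], cfg)

    def test_sampled_p_close_to_exhaustive_on_small_universe(self):
        rng = np.random.default_rng(5)
        u = universe(rng.normal(size=10))
        observed = list(u.sort_values().index[:3])
        exact = permutation_median_test(
            u, observed,
            PermutationConfig(n_random_sets=1, set_size=3, mode="exhaustive"),
        )
        sampled = permutation_median_test(
            u, observed,
            PermutationConfig(n_random_sets=20_000, set_size=3, seed=3),
        )
        assert abs(sampled.p_le - exact.p_le) < 0.02


# ---------------------------------------------------------------------------
# rank tests vs enumeration oracles


def wilcoxon_enum_oracle(x):
    """Two-sided signed-rank p by brute-force sign enumeration (midranks)."""
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    ranks = stats.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    ws = [np.sum(ranks[np.array(signs) > 0])
          for signs in product([-1, 1], repeat=len(x))]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def ranksum_enum_oracle(a, b):
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    r_obs = ranks[:na].sum()
    sums = [ranks[list(idx)].sum()
            for idx in combinations(range(len(pooled)), na)]
    sums = np.array(sums)
    return min(1.0, 2 * min(np.mean(sums <= r_obs), np.mean(sums >= r_obs)))


class TestWilcoxonDepartureFromZero:
    def test_all_zeros_is_uninformative(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_departure_from_zero([0.0, 0.0, 0.0]) == 1.0

    def test_three_positive_values(self):
        assert wilcoxon_departure_from_zero([1, 2, 3]) == pytest.approx(0.25)

    def test_exact_matches_full_enumeration_n12(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.3, 1.0, size=12)
        assert wilcoxon_departure_from_zero(x) == pytest.approx(
            wilcoxon_enum_oracle(x), abs=1e-12
        )

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=10))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_exact_matches_enumeration_with_ties(self, values):
        x = np.asarray(values, dtype=float)
        if np.all(x == 0):
            return
        assert wilcoxon_departure_from_zero(x) == pytest.approx(
            wilcoxon_enum_oracle(x), abs=1e-9
        )

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1.0, size=60)
        p = wilcoxon_departure_from_zero(x)
        ref = stats.wilcoxon(x, alternative="two-sided",
                             method="approx", correction=False).pvalue
        assert p == pytest.approx(ref)


class TestRanksumCompare:
    def test_identical_multisets_have_no_separation(self):
        assert ranksum_compare([1, 2, 3, 4], [1, 2, 3, 4]) >= 0.99

    def test_disjoint_extreme_groups(self):
        assert ranksum_compare([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_exact_matches_enumeration(self, a, b):
        assert ranksum_compare(a, b) == pytest.approx(
            ranksum_enum_oracle(np.asarray(a, float), np.asarray(b, float)),
            abs=1e-9,
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([], [1, 2])


class TestKsSetVsNull:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 20)
        d, p = ks_set_vs_null(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_give_maximal_d(self):
        d, _ = ks_set_vs_null([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_d_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=15), rng.normal(0.8, 1.2, size=25)
        d, _ = ks_set_vs_null(a, b)
        grid = np.concatenate([a, b])
        d_oracle = max(
            abs(np.mean(a <= t) - np.mean(b <= t)) for t in grid
        )
        assert d == pytest.approx(d_oracle)


def test_compute_quantity_igr_matches_pairing_distance(small_sim):
    _, ann, _, _ = small_sim
    from termsig.annotation import upstream_same_strand_partner

    values = compute_quantity(ann, "igr")
    for gid in list(values.index)[:30]:
        pairing = upstream_same_strand_partner(ann, gid)
        assert values[gid] == pairing.distance_bp
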