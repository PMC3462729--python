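"""Unit and property tests for the seven consistency metrics."""

import math

import numpy as np
import pytest

from gsc import (
    GeneSet,
    abs_spread,
    corr_summary,
    diff_spread,
    evaluate_collections,
    evaluate_set,
    pc1_fraction,
    sample_array_pairs,
)
from gsc.io_formats import GeneSetCollection
from gsc.metrics import derive_seed, subsample_genes

from _oracles import (
    brute_abs_spread,
    brute_corr_summary,
    brute_diff_spread,
    brute_pc1,
)
from conftest import make_matrix, make_set


class TestSampleArrayPairs:
    def test_small_p_is_exhaustive(self):
        ps = sample_array_pairs(3, n_pairs=100, seed=0)
        assert ps.exhaustive
        assert sorted(ps.pairs) == [(0, 1), (0, 2), (1, 2)]

    def test_deterministic_under_seed(self):
        a = sample_array_pairs(50, n_pairs=100, seed=42)
        b = sample_array_pairs(50, n_pairs=100, seed=42)
        assert a.pairs == b.pairs
        assert not a.exhaustive
        assert len(a) == 100

    def test_pairs_distinct_and_oriented(self):
        ps = sample_array_pairs(30, n_pairs=100, seed=7)
        assert len(set(ps.pairs)) == 100
        assert all(k < l for k, l in ps.pairs)

    def test_rejects_single_array(self):
        with pytest.raises(ValueError):
            sample_array_pairs(1, seed=0)

    def test_inclusion_frequency_uniform(self):
        # each of the 66 pairs of 12 arrays should enter a 10-pair draw
        # with probability 10/66; check empirical frequency over many
        # seeded draws against a 5-sigma binomial band
        P, n_pairs, n_draws = 12, 10, 4000
        total = P * (P - 1) // 2
        counts = {}
        for seed in range(n_draws):
            for pair in sample_array_pairs(P, n_pairs=n_pairs, seed=seed).pairs:
                counts[pair] = counts.get(pair, 0) + 1
        p = n_pairs / total
        band = 5 * math.sqrt(n_draws * p * (1 - p))
        assert len(counts) == total
        for c in counts.values():
            assert abs(c - n_draws * p) < band


class TestDiffSpread:
    def test_parallel_profiles_give_zero(self):
        m = make_matrix([[1.0, 3.0, 2.0], [1.0, 3.0, 2.0]])
        ps = sample_array_pairs(3, seed=0)
        smd, smdd = diff_spread(make_set(m), m, ps)
        assert smd == pytest.approx(0.0, abs=1e-15)
        assert smdd == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_profiles_give_zero(self):
        # A=(1,3), B=(5,7): d = (-2, -2) for the single pair, SD 0
        m = make_matrix([[1.0, 3.0], [5.0, 7.0]])
        ps = sample_array_pairs(2, seed=0)
        smd, smdd = diff_spread(make_set(m), m, ps)
        assert smd == 0.0 and smdd == 0.0

    def test_matches_brute_force_exhaustive(self, rng):
        rows = rng.normal(7, 1, size=(4, 6))
        m = make_matrix(rows)
        ps = sample_array_pairs(6, n_pairs=100, seed=0)
        assert ps.exhaustive and len(ps) == 15
        got = diff_spread(make_set(m), m, ps)
        exp = brute_diff_spread(rows.tolist(), ps.pairs)
        assert got[0] == pytest.approx(exp[0], abs=1e-10)
        assert got[1] == pytest.approx(exp[1], abs=1e-10)

    def test_invariant_under_array_relabeling(self, rng):
        rows = rng.normal(0, 1, size=(5, 7))
        perm = rng.permutation(7)
        m1, m2 = make_matrix(rows), make_matrix(rows[:, perm])
        ps = sample_array_pairs(7, n_pairs=100, seed=0)  # exhaustive: 21
        assert diff_spread(make_set(m1), m1, ps) == pytest.approx(
            diff_spread(make_set(m2), m2, ps)
        )

    def test_invariant_under_array_column_shift(self, rng):
        # adding a constant to one array's column shifts all d_i for
        # pairs touching it equally, leaving every SD unchanged
        rows = rng.normal(0, 1, size=(5, 6))
        shifted = rows.copy()
        shifted[:, 2] += 3.7
        m1, m2 = make_matrix(rows), make_matrix(shifted)
        ps = sample_array_pairs(6, n_pairs=100, seed=0)
        assert diff_spread(make_set(m1), m1, ps) == pytest.approx(
            diff_spread(make_set(m2), m2, ps)
        )

    def test_rejects_empty_pairs(self, random_matrix):
        from gsc.metrics import PairSample

        with pytest.raises(ValueError):
            diff_spread(
                make_set(random_matrix),
                random_matrix,
                PairSample(pairs=(), exhaustive=False, seed=0),
            )

    def test_sampled_estimator_unbiased(self, rng):
        # mean of many seeded 20-pair estimates approaches the
        # exhaustive value on a 15-array matrix (105 pairs)
        rows = rng.normal(7, 1, size=(6, 15))
        m = make_matrix(rows)
        s = make_set(m)
        exhaustive, _ = diff_spread(s, m, sample_array_pairs(15, n_pairs=105, seed=0))
        estimates = [
            diff_spread(s, m, sample_array_pairs(15, n_pairs=20, seed=seed))[0]
            for seed in range(300)
        ]
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - exhaustive) < 4 * se


class TestAbsSpread:
    def test_identical_values_give_zero(self):
        m = make_matrix([[4.0, 5.0, 6.0], [4.0, 5.0, 6.0]])
        assert abs_spread(make_set(m), m) == (0.0, 0.0)

    def test_two_gene_hand_example(self):
        # per-array SDs of {1,5} and {3,7} are both sqrt(8)
        m = make_matrix([[1.0, 3.0], [5.0, 7.0]])
        sme, smed = abs_spread(make_set(m), m)
        assert sme == pytest.approx(math.sqrt(8.0), abs=1e-12)
        assert smed == pytest.approx(math.sqrt(8.0), abs=1e-12)

    def test_matches_brute_force(self, rng):
        rows = rng.normal(7, 2, size=(5, 8))
        m = make_matrix(rows)
        got = abs_spread(make_set(m), m)
        exp = brute_abs_spread(rows.tolist())
        assert got == pytest.approx(exp, abs=1e-10)


class TestCorrSummary:
    def test_affine_dependence_gives_one(self):
        m = make_matrix([[0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0]])
        cm, cmed = corr_summary(make_set(m), m, seed=0)
        assert cm == pytest.approx(1.0)
        assert cmed == pytest.approx(1.0)

    def test_three_gene_hand_example(self):
        # r_AB=1, r_AC=-1, r_BC=-1 -> mean -1/3, median -1
        m = make_matrix([[0, 1, 2], [0, 2, 4], [2, 1, 0]])
        cm, cmed = corr_summary(make_set(m), m, seed=0)
        assert cm == pytest.approx(-1.0 / 3.0, abs=1e-12)
        assert cmed == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_pairs_excluded(self, rng):
        rows = np.vstack([rng.normal(0, 1, size=(3, 6)), np.full((1, 6), 5.0)])
        m = make_matrix(rows)
        got = corr_summary(make_set(m), m, seed=0)
        exp = brute_corr_summary(rows.tolist())  # 3 defined pairs
        assert got == pytest.approx(exp, abs=1e-10)

    def test_all_constant_set_is_undefined(self):
        m = make_matrix([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        cm, cmed = corr_summary(make_set(m), m, seed=0)
        assert math.isnan(cm) and math.isnan(cmed)

    def test_subsample_matches_brute_force_on_same_subset(self, rng):
        # a 60-gene set is reduced to a seeded 50-gene subset; the
        # result must equal brute-force Pearson on that same subset
        rows = rng.normal(7, 1, size=(60, 10))
        m = make_matrix(rows)
        s = make_set(m)
        subset = subsample_genes(s, 50, seed=99)
        assert len(subset) == 50
        got = corr_summary(s, m, max_genes=50, seed=99)
        idx = [m.gene_ids.index(g) for g in subset]
        exp = brute_corr_summary(rows[idx].tolist())
        assert got == pytest.approx(exp, abs=1e-10)

    def test_invariant_to_per_gene_constant_shift(self, rng):
        rows = rng.normal(0, 1, size=(4, 8))
        shifted = rows + rng.normal(0, 5, size=(4, 1))
        m1, m2 = make_matrix(rows), make_matrix(shifted)
        assert corr_summary(make_set(m1), m1, seed=0) == pytest.approx(
            corr_summary(make_set(m2), m2, seed=0)
        )


class TestPc1Fraction:
    def test_two_gene_hand_example(self):
        # cov [[1,2],[2,4]] has eigenvalues (5, 0) -> pc1 = 1
        m = make_matrix([[0.0, 1.0, 2.0], [0.0, 2.0, 4.0]])
        assert pc1_fraction(make_set(m), m) == pytest.approx(1.0, abs=1e-12)

    def test_identical_genes_are_rank_one(self, rng):
        row = rng.normal(0, 1, size=10)
        m = make_matrix(np.tile(row, (5, 1)))
        assert pc1_fraction(make_set(m), m) == pytest.approx(1.0, abs=1e-12)

    def test_all_constant_set_is_undefined(self):
        m = make_matrix([[3.0, 3.0, 3.0], [1.0, 1.0, 1.0]])
        assert math.isnan(pc1_fraction(make_set(m), m))

    def test_matches_full_eigendecomposition(self, rng):
        rows = rng.normal(7, 1, size=(6, 20))
        m = make_matrix(rows)
        assert pc1_fraction(make_set(m), m) == pytest.approx(
            brute_pc1(rows.tolist()), abs=1e-10
        )

    def test_wide_set_more_genes_than_arrays(self, rng):
        rows = rng.normal(0, 1, size=(12, 5))
        m = make_matrix(rows)
        assert pc1_fraction(make_set(m), m) == pytest.approx(
            brute_pc1(rows.tolist()), abs=1e-10
        )

    def test_lower_bound_one_over_n(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            rows = rng.normal(0, 1, size=(n, 10))
            m = make_matrix(rows)
            v = pc1_fraction(make_set(m), m)
            assert 1.0 / n - 1e-12 <= v <= 1.0 + 1e-12

    def test_invariant_to_per_gene_constant_shift(self, rng):
        rows = rng.normal(0, 1, size=(4, 9))
        shifted = rows + rng.normal(0, 5, size=(4, 1))
        m1, m2 = make_matrix(rows), make_matrix(shifted)
        assert pc1_fraction(make_set(m1), m1) == pytest.approx(
            pc1_fraction(make_set(m2), m2), abs=1e-12
        )


class TestEvaluateCollections:
    def _collection(self, matrix, sizes, source="SRC"):
        gene_pool = matrix.gene_ids
        sets, start = [], 0
        for i, n in enumerate(sizes):
            sets.append(
                GeneSet(
                    set_id=f"{source}_{i}",
                    genes=frozenset(gene_pool[start : start + n]),
                    source=source,
                )
            )
            start += n
        return GeneSetCollection(organism=matrix.organism, source=source, sets=tuple(sets))

    def test_two_gene_set_fully_populated(self, rng):
        m = make_matrix(rng.normal(7, 1, size=(2, 6)))
        recs = evaluate_collections([self._collection(m, [2])], m, seed=0)
        (r,) = recs
        for name in ("s_mean_diff", "s_median_diff", "s_mean_exp", "s_median_exp",
                     "corr_mean", "corr_median", "pc1"):
            assert math.isfinite(r.metric(name))

    def test_determinism(self, rng):
        m = make_matrix(rng.normal(7, 1, size=(20, 10)))
        coll = self._collection(m, [3, 5, 4])
        a = evaluate_collections([coll], m, seed=5)
        b = evaluate_collections([coll], m, seed=5)
        assert a == b

    def test_composition_matches_single_set_calls(self, rng):
        m = make_matrix(rng.normal(7, 1, size=(60, 12)))
        coll = self._collection(m, [2, 3, 4, 5, 6, 8, 10, 12, 4, 6])
        recs = evaluate_collections([coll], m, n_pairs=30, seed=11)
        pairs = sample_array_pairs(12, n_pairs=30, seed=11)
        for rec, s in zip(recs, coll.sets):
            single = evaluate_set(s, m, pairs, seed=derive_seed(11, s.set_id))
            assert rec == single

    def test_adding_a_set_never_changes_others(self, rng):
        m = make_matrix(rng.normal(7, 1, size=(120, 8)))
        base = self._collection(m, [55, 60])  # both above the 50-gene cap
        extended = self._collection(m, [55, 60, 5])
        a = evaluate_collections([base], m, seed=3)
        b = evaluate_collections([extended], m, seed=3)
        assert a == b[: len(a)]

    def test_degenerate_set_yields_nan_not_abort(self, rng):
        rows = np.vstack([np.ones((2, 6)), rng.normal(0, 1, size=(2, 6))])
        m = make_matrix(rows)
        coll = self._collection(m, [2, 2])
        recs = evaluate_collections([coll], m, seed=0)
        assert math.isnan(recs[0].corr_mean) and math.isnan(recs[0].pc1)
        assert math.isfinite(recs[1].corr_mean)
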