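"""Binarization, run-length statistics and the Bernoulli independent-cell null."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from filafluct.datatypes import BinaryFilament, FilamentSet, FilamentTrace
from filafluct import cluster_analysis as ca

from _oracles import bernoulli_run_distribution_exact, run_sizes_loop


def make_set(list_of_values):
    return FilamentSet(
        [FilamentTrace(np.asarray(v, float), i) for i, v in enumerate(list_of_values)]
    )


class TestBinarize:
    def test_upper_15_percent_of_1_to_100(self):
        fset = make_set([np.arange(1.0, 101.0)])
        bits, thr = ca.binarize(fset, ca.BinarizationParams(percentile=0.15))
        assert thr == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.85))
        assert bits[0].bits.sum() == 15  # values 86..100 strictly above 85.15

    def test_all_equal_values_yield_no_ones(self):
        bits, _ = ca.binarize(make_set([[5.0] * 20]))
        assert bits[0].bits.sum() == 0

    def test_monotone_transform_preserves_bit_pattern(self, rng):
        vals = rng.gamma(4, 3, size=60)
        a, _ = ca.binarize(make_set([vals]))
        b, _ = ca.binarize(make_set([np.exp(vals / 10)]))
        assert np.array_equal(a[0].bits, b[0].bits)

    def test_percentile_bounds_enforced(self):
        with pytest.raises(ValueError):
            ca.BinarizationParams(percentile=1.5)


class TestClusterSizes:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ([0, 1, 1, 0, 1], [2, 1]),
            ([0, 0, 0], []),
            ([1, 1, 1, 1], [4]),
            ([1, 0, 1], [1, 1]),
            ([], []),
        ],
    )
    def test_run_length_definition(self, bits, expected):
        got = sorted(ca.cluster_sizes(np.array(bits, dtype=np.int8)).tolist())
        assert got == sorted(expected)

    @given(st.lists(st.integers(0, 1), max_size=40))
    def test_matches_scan_oracle_and_conserves_ones(self, bits):
        arr = np.array(bits, dtype=np.int8)
        sizes = ca.cluster_sizes(arr)
        assert sorted(sizes.tolist()) == sorted(run_sizes_loop(bits))
        assert sizes.sum() == arr.sum()

    @given(st.lists(st.integers(0, 1), max_size=40))
    def test_reversal_invariance(self, bits):
        arr = np.array(bits, dtype=np.int8)
        assert sorted(ca.cluster_sizes(arr).tolist()) == sorted(
            ca.cluster_sizes(arr[::-1]).tolist()
        )


class TestClusterSizeHistogram:
    def test_counts_per_integer_size(self):
        h = ca.cluster_size_histogram(np.array([2, 1, 1]))
        assert h.counts.tolist() == [2, 1]

    def test_empty_input_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            h = ca.cluster_size_histogram(np.empty(0, dtype=int))
        assert h.total == 0

    def test_pooling_is_concatenation(self):
        a, b = np.array([1, 2]), np.array([2, 3])
        pooled = ca.cluster_size_histogram([a, b])
        concat = ca.cluster_size_histogram(np.concatenate([a, b]))
        assert np.array_equal(pooled.counts, concat.counts)


class TestBernoulliStrings:
    def test_p_zero_all_zeros(self):
        strs = ca.simulate_bernoulli_strings(
            ca.BernoulliSimParams(n_strings=10, string_length=20, p=0.0, seed=0)
        )
        assert all(s.bits.sum() == 0 for s in strs)

    def test_p_one_single_full_cluster(self):
        strs = ca.simulate_bernoulli_strings(
            ca.BernoulliSimParams(n_strings=10, string_length=20, p=1.0, seed=0)
        )
        for s in strs:
            assert ca.cluster_sizes(s).tolist() == [20]

    def test_expected_run_counts_match_exact_enumeration(self):
        """Closed-form finite-L run-count law vs exhaustive 2^L enumeration."""
        for L, p in ((6, 0.15), (10, 0.3), (8, 0.5)):
            closed = ca.bernoulli_expected_run_counts(L, p)
            exact = bernoulli_run_distribution_exact(L, p)
            assert closed == pytest.approx(exact, abs=1e-12)

    def test_hit_fraction_and_size_law_at_study_conditions(self):
        """1000 strings x 20 cells, p = 0.15: the stated null simulation."""
        params = ca.BernoulliSimParams(n_strings=1000, string_length=20,
                                       p=0.15, seed=5)
        strs = ca.simulate_bernoulli_strings(params)
        bits = np.vstack([s.bits for s in strs])
        frac = bits.mean()
        se = np.sqrt(0.15 * 0.85 / bits.size)
        assert abs(frac - 0.15) < 3 * se
        sizes = np.concatenate([ca.cluster_sizes(s) for s in strs])
        gof = ca.cluster_law_gof(sizes, 20, 0.15)
        assert gof.p_value > 0.01

    def test_mean_cluster_size_approaches_geometric_limit(self):
        # E[size] -> 1/(1-p) ~ 1.176 at p = 0.15 as L grows
        e = ca.bernoulli_expected_run_counts(500, 0.15)
        k = np.arange(1, 501)
        assert (k * e).sum() / e.sum() == pytest.approx(1 / 0.85, abs=1e-3)


class TestCompareToIndependent:
    def test_identical_simulation_gives_zero_emd(self):
        params = ca.BernoulliSimParams(n_strings=300, string_length=20,
                                       p=0.15, seed=9)
        strs = ca.simulate_bernoulli_strings(params)
        sizes = np.concatenate([ca.cluster_sizes(s) for s in strs])
        res = ca.compare_to_independent(sizes, params, n_boot=200, seed=0)
        assert res.statistic == 0.0
        assert res.se > 0.0

    def test_independent_replicate_is_close_clustered_data_is_far(self):
        null = ca.BernoulliSimParams(n_strings=1000, string_length=20,
                                     p=0.15, seed=1)
        other = ca.BernoulliSimParams(n_strings=1000, string_length=20,
                                      p=0.15, seed=2)
        sizes_repl = np.concatenate(
            [ca.cluster_sizes(s) for s in ca.simulate_bernoulli_strings(other)]
        )
        res_repl = ca.compare_to_independent(sizes_repl, null, n_boot=300, seed=3)

        # strongly clustered bits: long alternating blocks
        rng = np.random.default_rng(4)
        blocks = []
        for _ in range(500):
            bits = np.zeros(20, dtype=np.int8)
            start = rng.integers(0, 14)
            if rng.random() < 0.45:
                bits[start : start + rng.integers(4, 7)] = 1
            blocks.append(bits)
        sizes_clust = np.concatenate([ca.cluster_sizes(b) for b in blocks])
        res_clust = ca.compare_to_independent(sizes_clust, null, n_boot=300, seed=5)

        assert res_repl.statistic < 3 * res_repl.se + 0.05
        assert res_clust.statistic > res_repl.statistic + 5 * res_clust.se

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="p = 0"):
            ca.compare_to_independent(
                np.array([1, 2]),
                ca.BernoulliSimParams(n_strings=10, string_length=5, p=0.0, seed=0),
            )
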