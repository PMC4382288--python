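"""Noise and autocorrelation statistics on filament traces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from filafluct.datatypes import CorrelationCurve, FilamentSet, FilamentTrace
from filafluct import filament_stats as fs
from filafluct import synthetic_data as sd

from _oracles import autocorr_double_loop


def make_set(list_of_values, run_id="run0"):
    return FilamentSet(
        [FilamentTrace(np.asarray(v, float), i, run_id)
         for i, v in enumerate(list_of_values)],
        run_id=run_id,
    )


# --------------------------------------------------------------------------
# population noise and decomposition
# --------------------------------------------------------------------------

class TestPopulationNoise:
    def test_hand_computed_two_cells(self):
        # cells {1, 3}: unbiased variance 2, mean 2 -> noise 0.5
        assert fs.population_noise(make_set([[1.0, 3.0]])) == pytest.approx(0.5)

    def test_constant_cells_give_zero(self):
        assert fs.population_noise(make_set([[2.0, 2.0], [2.0, 2.0]])) == 0.0

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, k):
        vals = [[1.0, 2.0, 5.0], [3.0, 4.0]]
        base = fs.population_noise(make_set(vals))
        scaled = fs.population_noise(make_set([[k * x for x in v] for v in vals]))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ValueError, match="mean"):
            fs.population_noise(make_set([[0.0, 0.0]]))


class TestNoiseDecomposition:
    def test_iid_filaments_have_small_ratio(self):
        params = sd.TraceGenParams(
            n_filaments=400, within_kernel=(1.0,), filament_cv=0.0,
            cell_noise_sd=0.0, length_law=("uniform", 30, 40), seed=4,
        )
        fset, truth = sd.generate_traces(params)
        dec = fs.noise_decomposition(fset)
        # no real between-filament heterogeneity: only the 1/L sampling floor
        assert dec.ratio < 0.1
        assert dec.ratio == pytest.approx(truth.expected_ratio, abs=0.03)

    def test_internally_constant_filaments_flagged_undefined(self):
        with pytest.warns(UserWarning, match="ratio undefined"):
            dec = fs.noise_decomposition(make_set([[1.0, 1.0], [3.0, 3.0]]))
        assert dec.within_avg == 0.0
        assert dec.ratio is None

    def test_needs_two_filaments(self):
        with pytest.raises(ValueError):
            fs.noise_decomposition(make_set([[1.0, 2.0]]))


# --------------------------------------------------------------------------
# autocorrelation
# --------------------------------------------------------------------------

class TestAutocorrelationRaw:
    def test_normalization_identity_g0(self):
        g = fs.autocorrelation_raw(np.array([3.0, 1.0, 4.0, 1.0, 5.0]), 2)
        assert g[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_alternating_trace(self):
        # F=(1,2,1,2): mu=1.5, population variance 0.25, g(1) = -1
        g = fs.autocorrelation_raw(np.array([1.0, 2.0, 1.0, 2.0]), 1)
        assert g[1] == pytest.approx(-1.0, abs=1e-12)

    def test_reversal_symmetry(self, rng):
        v = rng.gamma(4.0, 1.0, size=17)
        assert fs.autocorrelation_raw(v, 5) == pytest.approx(
            fs.autocorrelation_raw(v[::-1], 5), abs=1e-12
        )

    @given(
        arrays(np.float64, st.integers(6, 30),
               elements=st.floats(0.1, 50.0)),
    )
    def test_matches_double_loop_oracle(self, v):
        if np.ptp(v) < 1e-3:  # near-constant traces: roundoff dominates
            return
        n_max = min(5, v.size - 1)
        got = fs.autocorrelation_raw(v, n_max)
        want = autocorr_double_loop(v, n_max)
        assert got == pytest.approx(want, abs=1e-12)

    @given(st.floats(0.5, 20.0), st.floats(0.0, 30.0))
    def test_affine_invariance(self, a, b):
        v = np.array([2.0, 7.0, 3.0, 9.0, 4.0, 6.0, 1.0, 8.0])
        assert fs.autocorrelation_raw(a * v + b, 3) == pytest.approx(
            fs.autocorrelation_raw(v, 3), rel=1e-9, abs=1e-9
        )

    def test_constant_trace_rejected(self):
        with pytest.raises(fs.ZeroVarianceError):
            fs.autocorrelation_raw(np.full(10, 3.0), 2)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fs.autocorrelation_raw(np.array([1.0, 2.0]), 3)


class TestAutocorrelationCorrected:
    def test_iid_raw_is_negatively_biased_and_correction_removes_it(self):
        """For independent cells the permuted curve equals the bias exactly."""
        raw1, corr1 = [], []
        for seed in range(8):
            params = sd.TraceGenParams(
                n_filaments=150, length_law=("fixed", 20),
                within_kernel=(1.0,), filament_cv=0.0, cell_noise_sd=0.0,
                seed=seed,
            )
            fset, _ = sd.generate_traces(params)
            corrected, raw, _ = fs.autocorrelation_corrected(
                fset, 3, seed=seed, return_components=True
            )
            raw1.append(raw.g[1])
            corr1.append(corrected.g[1])
        raw1, corr1 = np.array(raw1), np.array(corr1)
        se = corr1.std(ddof=1) / np.sqrt(corr1.size)
        # iid bias is -1/(L-1) ~ -0.053 at L=20
        assert raw1.mean() < -0.03
        assert abs(corr1.mean()) < 3 * se

    def test_shuffled_data_stays_at_zero(self, rng):
        params = sd.TraceGenParams(n_filaments=200, cell_noise_sd=0.0, seed=9)
        fset, _ = sd.generate_traces(params)
        shuffled = FilamentSet(
            [FilamentTrace(rng.permutation(t.values), t.filament_id)
             for t in fset],
            run_id="shuffled",
        )
        curve = fs.autocorrelation_corrected(shuffled, 5, seed=1)
        assert np.all(np.abs(curve.g[1:]) < 4 * np.maximum(curve.se[1:], 1e-3))

    def test_long_filament_convergence_to_kernel_autocorrelation(self):
        """Bias ~ 1/L: at L = 200 the permutation-corrected curve matches."""
        params = sd.TraceGenParams(
            n_filaments=200, length_law=("fixed", 200),
            within_kernel=(1.0, 1.0, 1.0), filament_cv=0.0,
            cell_noise_sd=0.0, seed=21,
        )
        fset, truth = sd.generate_traces(params)
        curve = fs.autocorrelation_corrected(fset, 5, seed=2)
        rho = np.zeros(6)
        rho[:3] = truth.kernel_autocorrelation
        rho[0] = 1.0
        assert np.all(np.abs(curve.g - rho) <= 3 * np.maximum(curve.se, 1e-4))

    def test_surrogate_method_recovers_kernel_on_short_filaments(self):
        """Surrogate compensation removes the correlation-dependent residual
        that plain permutation subtraction leaves on 8-40 cell filaments."""
        params = sd.TraceGenParams(
            n_filaments=300, filament_cv=0.0, cell_noise_sd=0.0, seed=11,
        )
        fset, truth = sd.generate_traces(params)
        perm = fs.autocorrelation_corrected(fset, 5, seed=3)
        surr = fs.autocorrelation_corrected(fset, 5, seed=3, method="surrogate")
        rho = np.zeros(6)
        rho[:3] = truth.kernel_autocorrelation
        # surrogate lands within its propagated 3 se; permutation does not at n=2
        assert np.all(np.abs(surr.g[1:] - rho[1:]) <= 3 * surr.se[1:])
        assert abs(perm.g[2] - rho[2]) > 3 * perm.se[2]

    def test_invalid_permutation_count(self):
        fset, _ = sd.generate_traces(sd.TraceGenParams(n_filaments=5, seed=0))
        with pytest.raises(ValueError):
            fs.autocorrelation_corrected(fset, 3, n_permutations=0)


# --------------------------------------------------------------------------
# neighbour pairs and aggregation
# --------------------------------------------------------------------------

class TestNeighborPairs:
    def test_alternating_filaments_are_anticorrelated(self):
        fset = make_set([[1.0, 9.0] * 6, [2.0, 8.0] * 5])
        assert fs.neighbor_pairs(fset).pearson_r < -0.9

    def test_iid_cells_near_zero(self):
        params = sd.TraceGenParams(
            n_filaments=300, within_kernel=(1.0,), filament_cv=0.0,
            cell_noise_sd=0.0, seed=2,
        )
        fset, _ = sd.generate_traces(params)
        pairs = fs.neighbor_pairs(fset)
        assert abs(pairs.pearson_r) < 3.0 / np.sqrt(pairs.n_pairs)

    def test_duplicating_filaments_leaves_r_unchanged(self):
        vals = [[1.0, 4.0, 2.0, 6.0, 3.0], [2.0, 5.0, 1.0, 7.0]]
        r1 = fs.neighbor_pairs(make_set(vals)).pearson_r
        r2 = fs.neighbor_pairs(make_set(vals + vals)).pearson_r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_margin_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fs.neighbor_pairs(make_set([[1.0, 1.0, 1.0]]))


class TestAggregateRuns:
    def _curve(self, g1):
        return CorrelationCurve(
            np.arange(2), np.array([1.0, g1]), np.zeros(2),
            corrected=True, n_filaments_used=10,
        )

    def test_hand_computed_mean_and_se(self):
        agg = fs.aggregate_runs([self._curve(0.2), self._curve(0.3)])
        assert agg.g[1] == pytest.approx(0.25)
        assert agg.se[1] == pytest.approx(0.05)

    def test_identical_runs_have_zero_se(self):
        agg = fs.aggregate_runs([self._curve(0.2), self._curve(0.2)])
        assert agg.se[1] == 0.0

    def test_single_run_flagged(self):
        with pytest.warns(UserWarning, match="single-run"):
            agg = fs.aggregate_runs([self._curve(0.4)])
        assert agg.g[1] == pytest.approx(0.4)
        assert np.all(agg.se == 0.0)

    def test_mismatched_grids_rejected(self):
        other = CorrelationCurve(
            np.arange(3), np.array([1.0, 0.1, 0.0]), np.zeros(3),
            corrected=True, n_filaments_used=10,
        )
        with pytest.raises(ValueError, match="grid"):
            fs.aggregate_runs([self._curve(0.2), other])
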