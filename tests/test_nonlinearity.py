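"""Theta scan, surrogates, and the delta-MAE randomization test."""

import numpy as np
import pytest
from helpers import make_prepared
from scipy import stats

from dynasig.edm_core import EmbeddingConfig, simplex_loocv
from dynasig.errors import ParameterError
from dynasig.nonlinearity_test import (
    DEFAULT_THETA_GRID,
    ThetaScan,
    apply_rho_screen,
    make_surrogate,
    nonlinearity_randomization_test,
    theta_scan,
)
from dynasig.series_prep import first_difference, standardize
from dynasig.synthetic_data import GeneratorSpec, generate_map_series


def _prepared_ar1(seed, n=200, phi=0.5):
    raw = generate_map_series(
        GeneratorSpec(kind="ar1", n=n, params={"phi": phi}, seed=seed, burn_in=50)
    )
    return make_prepared(first_difference(standardize(raw.values)), sid=f"ar1-{seed}")


class TestThetaScan:
    def test_delta_mae_definition(self):
        scan = ThetaScan.from_metrics(
            thetas=[0.0, 0.5, 1.0],
            mae=[0.5, 0.45, 0.4],
            rho=[0.1, 0.2, 0.3],
        )
        assert scan.delta_mae == pytest.approx(0.1)
        assert scan.best_theta == 1.0

    def test_scan_length_matches_grid(self):
        ps = _prepared_ar1(0, n=80)
        scan = theta_scan(ps, E=2)
        assert len(scan.thetas) == len(DEFAULT_THETA_GRID)
        assert len(scan.mae_by_theta) == len(DEFAULT_THETA_GRID)
        assert scan.thetas[0] == 0.0

    def test_linear_noise_free_series_has_nonpositive_delta(self):
        # sine obeys a 2-lag linear recurrence exactly: theta = 0 is optimal
        w = 2 * np.pi / 19
        t = np.arange(150.0)
        ps = make_prepared(np.sin(w * t + 0.7))
        scan = theta_scan(ps, E=2)
        assert scan.delta_mae <= 1e-6

    def test_grid_must_contain_zero_and_positive(self):
        ps = _prepared_ar1(1, n=60)
        with pytest.raises(ParameterError):
            theta_scan(ps, E=2, theta_grid=[0.5, 1.0])
        with pytest.raises(ParameterError):
            theta_scan(ps, E=2, theta_grid=[0.0])


class TestSurrogates:
    def test_values_are_a_permutation(self):
        ps = _prepared_ar1(3, n=60)
        sur = make_surrogate(ps, seed=9)
        np.testing.assert_allclose(np.sort(sur.values), np.sort(ps.values))

    def test_seed_determinism(self):
        ps = _prepared_ar1(3, n=60)
        a = make_surrogate(ps, seed=11)
        b = make_surrogate(ps, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shuffle_destroys_autocorrelation(self):
        raw = generate_map_series(
            GeneratorSpec(kind="ar1", n=300, params={"phi": 0.8}, seed=5, burn_in=50)
        )
        ps = make_prepared(standardize(raw.values))
        r1s = []
        for seed in range(200):
            s = make_surrogate(ps, seed=seed).values
            r1s.append(np.corrcoef(s[:-1], s[1:])[0, 1])
        assert abs(np.mean(r1s)) < 0.05

    def test_phase_surrogate_preserves_amplitudes(self):
        ps = _prepared_ar1(4, n=64)
        sur = make_surrogate(ps, seed=2, scheme="phase")
        np.testing.assert_allclose(np.sort(sur.values), np.sort(ps.values))


class TestRhoScreen:
    def _result(self, rho, p_rho):
        from dynasig.edm_core import ForecastResult

        return ForecastResult(
            predictions=np.zeros(3), observed=np.zeros(3), rho=rho, mae=0.1,
            rmse=0.1, p_rho=p_rho, E=2, theta=0.0, n_pred=3,
        )

    def test_significant_series_retained(self):
        assert apply_rho_screen(self._result(0.5, 0.04)) == (False, None)

    def test_boundary_p_value_screened(self):
        screened, reason = apply_rho_screen(self._result(0.5, 0.05))
        assert screened and "p_rho" in reason

    def test_negative_rho_screened_regardless_of_p(self):
        screened, reason = apply_rho_screen(self._result(-0.2, 0.001))
        assert screened and "rho" in reason


class TestRandomizationTest:
    def test_screened_series_skips_surrogates(self):
        ps = _prepared_ar1(0, n=60)
        weak = TestRhoScreen()._result(rho=0.1, p_rho=0.6)
        res = nonlinearity_randomization_test(
            ps, E=2, n_surrogates=50, seed=1, screen_result=weak
        )
        assert res.screened_out and not res.is_nonlinear
        assert len(res.surrogate_deltas) == 0

    def test_p_value_positive_and_counts_match(self):
        ps = _prepared_ar1(7, n=100)
        res = nonlinearity_randomization_test(ps, E=3, n_surrogates=50, seed=4)
        assert 0.0 < res.p_value <= 1.0
        assert len(res.surrogate_deltas) == res.n_surrogates == 50

    def test_seed_reproducibility(self):
        ps = _prepared_ar1(8, n=100)
        a = nonlinearity_randomization_test(ps, E=2, n_surrogates=30, seed=12)
        b = nonlinearity_randomization_test(ps, E=2, n_surrogates=30, seed=12)
        np.testing.assert_array_equal(a.surrogate_deltas, b.surrogate_deltas)
        assert a.p_value == b.p_value

    def test_chaotic_series_detected(self):
        raw = generate_map_series(
            GeneratorSpec(kind="logistic_map", n=200, seed=6, burn_in=100,
                          obs_noise_sd=0.01)
        )
        ps = make_prepared(first_difference(standardize(raw.values)))
        best = simplex_loocv(ps, EmbeddingConfig(E=2))
        res = nonlinearity_randomization_test(
            ps, E=2, n_surrogates=100, seed=3, screen_result=best
        )
        assert not res.screened_out
        assert res.is_nonlinear

    def test_early_stop_same_classification(self):
        # halting once the linear call is decided never changes the verdict
        for seed in (0, 1, 4, 6):
            kind = "ar1" if seed % 2 == 0 else "logistic_map"
            raw = generate_map_series(
                GeneratorSpec(kind=kind, n=80, seed=seed, burn_in=50,
                              obs_noise_sd=0.02)
            )
            ps = make_prepared(first_difference(standardize(raw.values)))
            full = nonlinearity_randomization_test(ps, E=2, n_surrogates=60, seed=seed)
            fast = nonlinearity_randomization_test(
                ps, E=2, n_surrogates=60, seed=seed, early_stop=True
            )
            assert full.is_nonlinear == fast.is_nonlinear
            if not fast.truncated:
                assert full.p_value == fast.p_value
            else:
                assert fast.p_value >= 0.05

    def test_low_resolution_flag(self):
        ps = _prepared_ar1(9, n=60)
        res = nonlinearity_randomization_test(ps, E=2, n_surrogates=10, seed=1)
        assert res.low_resolution

    def test_null_p_values_approximately_uniform(self):
        # applying the test to already-shuffled series: p should be ~U(0, 1]
        grid = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0)
        ps_base = _prepared_ar1(10, n=60)
        rng = np.random.default_rng(77)
        pvals = []
        for k in range(200):
            shuffled = make_prepared(rng.permutation(ps_base.values), sid=f"sh{k}")
            # fixed E on both sides: observed and surrogate pipelines match
            res = nonlinearity_randomization_test(
                shuffled, E=2, theta_grid=grid, n_surrogates=24, seed=k,
                reselect_E=False,
            )
            pvals.append(res.p_value)
        # discrete null support {1/25, ..., 25/25}: compare against uniform
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.001
        assert 0.3 < np.mean(pvals) < 0.7
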