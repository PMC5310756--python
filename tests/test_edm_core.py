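"""Embedding, simplex projection, S-map, and forecast-skill metrics."""

import numpy as np
import pytest
from helpers import make_prepared

from dynasig.edm_core import (
    EmbeddingConfig,
    LagLibrary,
    embed,
    fisher_z_pvalue,
    select_E,
    simplex_forecast_one,
    simplex_loocv,
    smap_forecast,
)
from dynasig.errors import EmbeddingError, NeighborCountError, SampleSizeError
from dynasig.synthetic_data import GeneratorSpec, generate_map_series


class TestEmbed:
    def test_pair_count(self):
        lib = embed(np.arange(5.0) + 7, EmbeddingConfig(E=2))
        assert len(lib) == 3

    def test_too_short_raises(self):
        with pytest.raises(EmbeddingError):
            embed(np.arange(5.0), EmbeddingConfig(E=5))

    def test_first_vector_unrolled(self):
        # series [a, b, c, d], E=2: first vector (b, a), target c
        lib = embed(np.array([10.0, 20.0, 30.0, 40.0]), EmbeddingConfig(E=2))
        np.testing.assert_array_equal(lib.vectors[0], [20.0, 10.0])
        assert lib.targets[0] == 30.0
        assert lib.time_index[0] == 1

    def test_lag_structure_spot_check(self, rng):
        y = rng.normal(size=40)
        cfg = EmbeddingConfig(E=3, tau=2, tp=1)
        lib = embed(y, cfg)
        i = 4
        t = lib.time_index[i]
        np.testing.assert_array_equal(lib.vectors[i], [y[t], y[t - 2], y[t - 4]])
        assert lib.targets[i] == y[t + 1]


class TestSimplex:
    def test_hand_computed_two_neighbor_weights(self):
        # neighbors at d = (1, 2), targets (0, 1):
        # weights (e^-1, e^-2) -> prediction = e^-2 / (e^-1 + e^-2)
        vectors = np.array([[0.0], [1.0], [-2.0]])
        targets = np.array([5.0, 0.0, 1.0])
        lib = LagLibrary(vectors, targets, np.arange(3))
        pred = simplex_forecast_one(lib, 0)
        expected = (np.exp(-1) * 0.0 + np.exp(-2) * 1.0) / (np.exp(-1) + np.exp(-2))
        assert pred == pytest.approx(expected, abs=1e-12)
        assert pred == pytest.approx(0.2689, abs=1e-4)

    def test_zero_distance_neighbor_takes_all_weight(self):
        vectors = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [5.0, 5.0], [6.0, 1.0]])
        targets = np.array([9.9, 7.7, 1.0, 2.0, 3.0])
        lib = LagLibrary(vectors, targets, np.arange(5))
        assert simplex_forecast_one(lib, 0) == pytest.approx(7.7)

    def test_equal_targets_give_constant_prediction(self, rng):
        vectors = rng.normal(size=(10, 2))
        targets = np.full(10, 4.2)
        lib = LagLibrary(vectors, targets, np.arange(10))
        assert simplex_forecast_one(lib, 3) == pytest.approx(4.2)

    def test_too_few_neighbors(self):
        lib = LagLibrary(np.zeros((3, 3)), np.zeros(3), np.arange(3))
        with pytest.raises(NeighborCountError):
            simplex_forecast_one(lib, 0)

    def test_vectorized_matches_scalar(self, rng):
        y = rng.normal(size=60)
        cfg = EmbeddingConfig(E=3)
        lib = embed(y, cfg)
        res = simplex_loocv(y, cfg)
        for i in [0, 7, 20, len(lib) - 1]:
            assert res.predictions[i] == pytest.approx(
                simplex_forecast_one(lib, i), abs=1e-12
            )

    def test_prediction_is_convex_combination(self, rng):
        y = rng.normal(size=80)
        cfg = EmbeddingConfig(E=2)
        lib = embed(y, cfg)
        res = simplex_loocv(y, cfg)
        for i in range(len(lib)):
            d = np.sqrt(((lib.vectors - lib.vectors[i]) ** 2).sum(1))
            d[i] = np.inf
            nb = np.argsort(d)[:3]
            lo, hi = lib.targets[nb].min(), lib.targets[nb].max()
            assert lo - 1e-12 <= res.predictions[i] <= hi + 1e-12

    def test_sine_wave_near_perfect_skill(self):
        t = np.arange(200.0)
        y = np.sin(2 * np.pi * t / 20)
        res = simplex_loocv(y, EmbeddingConfig(E=2))
        assert res.rho >= 0.99

    def test_iid_noise_no_skill_on_average(self):
        rhos = []
        for seed in range(100):
            y = np.random.default_rng(seed).normal(size=200)
            rhos.append(simplex_loocv(y, EmbeddingConfig(E=3)).rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_prediction_count_equals_pair_count(self, rng):
        y = rng.normal(size=47)
        cfg = EmbeddingConfig(E=4)
        res = simplex_loocv(y, cfg)
        assert res.n_pred == len(embed(y, cfg)) == len(res.predictions)

    def test_loocv_excludes_own_target(self, rng):
        # perturbing the withheld pair's target must not move its prediction
        y = rng.normal(size=50)
        cfg = EmbeddingConfig(E=2)
        lib = embed(y, cfg)
        i = 10
        pred = simplex_forecast_one(lib, i)
        targets2 = lib.targets.copy()
        targets2[i] += 100.0
        lib2 = LagLibrary(lib.vectors, targets2, lib.time_index)
        assert simplex_forecast_one(lib2, i) == pytest.approx(pred, abs=1e-12)


class TestSelectE:
    def test_tie_breaks_to_smaller_E(self):
        # an alternating series is forecast exactly at every E (zero-distance
        # neighbors with equal targets), so rho ties at 1.0 and parsimony wins
        y = np.array([0.0, 1.0] * 30)
        best, scan = select_E(y, E_range=[2, 3])
        assert scan[2].rho == scan[3].rho == 1.0
        assert best == 2

    def test_scan_covers_feasible_range(self, rng):
        y = rng.normal(size=100)
        best, scan = select_E(y, E_max=8)
        assert set(scan) == set(range(1, 9))
        assert best in scan

    def test_no_feasible_E(self):
        with pytest.raises(EmbeddingError):
            select_E(np.arange(4.0), E_range=[8, 9])

    def test_two_lag_map_recovered(self):
        # Henon: x_{t+1} = 1 - a x_t^2 + b x_{t-1}, a genuinely 2-lag
        # chaotic map, should be embedded at E = 2 (or 3)
        rng = np.random.default_rng(5)
        x = np.empty(700)
        x[0], x[1] = rng.uniform(-0.1, 0.1, 2)
        for t in range(1, 699):
            x[t + 1] = 1 - 1.4 * x[t] ** 2 + 0.3 * x[t - 1]
        y = x[200:]
        y = (y - y.mean()) / y.std(ddof=1)
        best, _ = select_E(y)
        assert best in (2, 3)


class TestSmap:
    def test_theta_zero_matches_global_linear_oracle(self, rng):
        y = rng.normal(size=100)
        cfg = EmbeddingConfig(E=3)
        lib = embed(y, cfg)
        res = smap_forecast(y, cfg, theta=0.0)
        A = np.column_stack([np.ones(len(lib)), lib.vectors])
        for i in range(len(lib)):
            keep = np.arange(len(lib)) != i
            beta, *_ = np.linalg.lstsq(A[keep], lib.targets[keep], rcond=None)
            assert res.predictions[i] == pytest.approx(A[i] @ beta, abs=1e-8)

    def test_linear_map_recovered_exactly(self):
        # x_{t+1} = 2 cos(w) x_t - x_{t-1} generates a sine exactly, so the
        # global linear fit at theta = 0 contains the truth
        w = 2 * np.pi / 17
        x = np.empty(120)
        x[0], x[1] = np.sin(0.3), np.sin(0.3 + w)
        for t in range(1, 119):
            x[t + 1] = 2 * np.cos(w) * x[t] - x[t - 1]
        res = smap_forecast(x, EmbeddingConfig(E=2), theta=0.0)
        assert res.rho > 0.9999

    def test_larger_theta_changes_predictions(self, rng):
        y = generate_map_series(
            GeneratorSpec(kind="logistic_map", n=120, seed=1)
        ).values
        y = (y - y.mean()) / y.std(ddof=1)
        p0 = smap_forecast(y, EmbeddingConfig(E=2), 0.0).predictions
        p2 = smap_forecast(y, EmbeddingConfig(E=2), 2.0).predictions
        assert not np.allclose(p0, p2)

    def test_negative_theta_rejected(self, rng):
        from dynasig.errors import ParameterError

        with pytest.raises(ParameterError):
            smap_forecast(rng.normal(size=50), EmbeddingConfig(E=2), -1.0)

    def test_rho_invariant_to_affine_rescaling(self, rng):
        y = rng.normal(size=80)
        res = smap_forecast(y, EmbeddingConfig(E=2), 1.0)
        obs, pred = res.observed, res.predictions
        r1 = np.corrcoef(obs, pred)[0, 1]
        r2 = np.corrcoef(3 * obs + 5, 3 * pred + 5)[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestFisherZ:
    def test_null_rho_gives_half(self):
        assert fisher_z_pvalue(0.0, 30) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # atanh(0.5) * sqrt(27) = 2.854 -> upper-tail normal ~ 0.00216
        assert fisher_z_pvalue(0.5, 30) == pytest.approx(0.00216, abs=5e-5)

    def test_monotone_in_rho(self):
        ps = [fisher_z_pvalue(r, 50) for r in np.linspace(-0.9, 0.9, 19)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_saturation_and_small_n(self):
        assert fisher_z_pvalue(1.0, 30) == 0.0
        with pytest.raises(SampleSizeError):
            fisher_z_pvalue(0.5, 3)
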