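"""Fitting machinery: W-RMSE cost, CRS2-LM, bounded quasi-Newton, two-stage."""

import numpy as np
import pytest

from cardiotwin.optimize import (AbsorptionModel, crs2_lm_minimize,
                                 lbfgsb_refine, simulated_annealing,
                                 time_weights, w_mse, w_rmse)
from cardiotwin.params import AbsorptionParams
from cardiotwin.synthetic import generate_fitting_dataset


def sphere(x):
    return float(np.sum(x ** 2))


def rosenbrock(x):
    return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)


def rastrigin(x):
    return float(10 * x.size + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))


class TestWRmse:
    def test_perfect_prediction_costs_zero(self):
        t = np.array([1.0, 2.0, 4.0])
        obs = np.array([5.0, 3.0, 1.0])
        assert w_rmse(obs, obs, t) == 0.0

    def test_single_point_unit_weight(self):
        assert w_rmse(np.array([4.0]), np.array([1.0]), np.array([2.0])) == 3.0

    def test_uniform_weights_reduce_to_plain_rmse(self, rng):
        for _ in range(5):
            t = np.sort(rng.uniform(0.1, 24, 12))
            pred, obs = rng.uniform(0, 50, 12), rng.uniform(0, 50, 12)
            brute = np.sqrt(np.mean((pred - obs) ** 2))
            assert w_rmse(pred, obs, t, scheme="uniform") == pytest.approx(brute, rel=1e-12)

    def test_interval_weights_compensate_uneven_sampling(self):
        t = np.array([1.0, 2.0, 3.0, 10.0])
        w = time_weights(t, "interval")
        assert w == pytest.approx([0.5, 1.0, 4.0, 3.5])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            w_mse(np.ones(3), np.ones(4), np.arange(4))


class TestCrs2:
    def test_sphere_minimized_within_budget(self):
        finals = [crs2_lm_minimize(sphere, [(-5, 5)] * 2, n_iter=1500, rng_seed=s).fun
                  for s in range(20)]
        assert np.median(finals) < 1e-3

    def test_constant_objective_returns_in_bounds_point(self):
        r = crs2_lm_minimize(lambda x: 7.0, [(-1, 1), (2, 3)], n_iter=100, rng_seed=0)
        assert r.fun == 7.0
        assert -1 <= r.x[0] <= 1 and 2 <= r.x[1] <= 3

    def test_beats_pure_random_search_on_rosenbrock(self):
        wins = 0
        for seed in range(20):
            r = crs2_lm_minimize(rosenbrock, [(-5, 5)] * 2, n_iter=1500, rng_seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            samples = rng.uniform(-5, 5, size=(1500, 2))
            best_random = min(rosenbrock(s) for s in samples)
            wins += r.fun < best_random
        assert wins >= 15  # paired comparison, overwhelming majority

    def test_iterates_stay_in_bounds(self):
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        crs2_lm_minimize(probe, [(0.5, 2.0), (-1.0, 0.0)], n_iter=300, rng_seed=1)
        pts = np.array(seen)
        assert pts[:, 0].min() >= 0.5 and pts[:, 0].max() <= 2.0
        assert pts[:, 1].min() >= -1.0 and pts[:, 1].max() <= 0.0


class TestLbfgsbRefine:
    def test_quadratic_bowl(self):
        r = lbfgsb_refine(lambda x: float(np.sum((x - 0.7) ** 2)),
                          np.array([2.0, -2.0]), [(-5, 5)] * 2)
        assert np.allclose(r.x, 0.7, atol=1e-6)

    def test_bound_semantics(self):
        # inward gradient at the bound: moves inside
        r = lbfgsb_refine(lambda x: float((x[0] - 1.0) ** 2), np.array([0.0]),
                          [(0.0, 5.0)])
        assert r.x[0] == pytest.approx(1.0, abs=1e-6)
        # outward gradient: stays on the bound
        r2 = lbfgsb_refine(lambda x: float((x[0] + 1.0) ** 2), np.array([0.0]),
                           [(0.0, 5.0)])
        assert r2.x[0] == 0.0

    def test_never_worsens_the_start(self):
        r = lbfgsb_refine(rastrigin, np.array([0.5, -0.5]), [(-5.12, 5.12)] * 2)
        assert r.fun <= rastrigin(np.array([0.5, -0.5]))

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lbfgsb_refine(lambda x: float("nan"), np.array([0.0]), [(-1, 1)])


class TestTwoStage:
    def test_not_worse_than_either_stage_alone_on_multibasin(self):
        bounds = [(-5.12, 5.12)] * 2
        two_stage, global_only, local_only = [], [], []
        for seed in range(20):
            g = crs2_lm_minimize(rastrigin, bounds, n_iter=600, rng_seed=seed)
            two = lbfgsb_refine(rastrigin, g.x, bounds)
            rng = np.random.default_rng(seed)
            start = rng.uniform(-5.12, 5.12, 2)
            loc = lbfgsb_refine(rastrigin, start, bounds)
            two_stage.append(two.fun)
            global_only.append(g.fun)
            local_only.append(loc.fun)
        assert np.median(two_stage) <= np.median(global_only) + 1e-12
        assert np.median(two_stage) <= np.median(local_only) + 1e-12


class TestSimulatedAnnealing:
    def test_finds_sphere_minimum(self):
        r = simulated_annealing(sphere, np.array([4.0, -4.0]), [(-5, 5)] * 2,
                                n_iter=5000, rng_seed=0)
        assert r.fun < 0.1

    def test_seeded_determinism(self):
        a = simulated_annealing(rastrigin, np.array([3.0, 3.0]), [(-5.12, 5.12)] * 2,
                                n_iter=2000, rng_seed=4)
        b = simulated_annealing(rastrigin, np.array([3.0, 3.0]), [(-5.12, 5.12)] * 2,
                                n_iter=2000, rng_seed=4)
        assert np.array_equal(a.x, b.x) and a.fun == b.fun


class TestAbsorptionFit:
    def test_noise_free_recovery_within_two_percent(self, model):
        truth = AbsorptionParams(ka=0.24, t_lag=1.33, F=model.absorption.F,
                                 fa_Fg=model.absorption.fa_Fg)
        obs, regimens, _ = generate_fitting_dataset(model, truth=truth,
                                                    noise_cv=0.0,
                                                    noise_floor_ngml=0.0, seed=0)
        fit = AbsorptionModel(obs, model, regimens).fit(seed=0)
        assert fit.ka == pytest.approx(0.24, rel=0.02)
        assert fit.t_lag == pytest.approx(1.33, rel=0.02)
        assert fit.w_rmse_final <= fit.w_rmse_initial

    def test_two_stage_pipeline_seed_deterministic(self, model):
        obs, regimens, _ = generate_fitting_dataset(model, seed=4)
        a = AbsorptionModel(obs, model, regimens).fit(seed=11, n_iter_global=200)
        b = AbsorptionModel(obs, model, regimens).fit(seed=11, n_iter_global=200)
        assert a.ka == b.ka and a.t_lag == b.t_lag

    def test_final_cost_never_exceeds_initial(self, model):
        for seed in range(3):
            obs, regimens, _ = generate_fitting_dataset(model, seed=seed)
            fit = AbsorptionModel(obs, model, regimens).fit(seed=seed,
                                                            n_iter_global=300)
            assert fit.w_rmse_final <= fit.w_rmse_initial

    def test_estimates_within_bounds_and_summary_renders(self, model):
        obs, regimens, _ = generate_fitting_dataset(model, seed=1)
        fit = AbsorptionModel(obs, model, regimens).fit(seed=1, n_iter_global=200)
        assert 0.1 <= fit.ka <= 2.0 and 0.0 <= fit.t_lag <= 2.0
        assert "W-RMSE" in fit.summary()
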