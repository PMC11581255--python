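"""Hawk/shepherd metaheuristic: update equations, chaotic energy,
Levy flights and whole-run contracts."""

import numpy as np
import pytest

from mihawk import optimizer as opt


class TestLogisticMap:
    @pytest.mark.parametrize("phi,a,expect", [
        (0.5, 4.0, 1.0), (0.75, 4.0, 0.75), (0.0, 3.1, 0.0)])
    def test_known_values(self, phi, a, expect):
        assert opt.logistic_step(phi, a) == pytest.approx(expect, abs=1e-15)

    @pytest.mark.parametrize("phi,a", [(-0.1, 4.0), (1.1, 4.0), (0.5, 4.5),
                                       (0.5, 0.0)])
    def test_domain_errors(self, phi, a):
        with pytest.raises(ValueError):
            opt.logistic_step(phi, a)


class TestEscapeEnergy:
    def test_zero_at_final_iteration(self):
        assert opt.escape_energy(0.9, 0.5, 100, 100) == 0.0

    def test_initial_magnitude(self):
        assert opt.escape_energy(1.0, 1.0, 0, 50) == 2.0

    def test_midpoint_arithmetic(self):
        assert opt.escape_energy(-1.0, 0.5, 50, 100) == pytest.approx(-0.5)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError):
            opt.escape_energy(1.0, 0.5, 0, 0)


class TestBoostedReference:
    def test_identical_inputs_fixed_point(self):
        v = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(opt.boosted_srand(v, v, v), v)

    def test_mean_of_three(self):
        np.testing.assert_allclose(
            opt.boosted_srand(np.array([3.0]), np.array([0.0]),
                              np.array([0.0])), [1.0])

    def test_linearity(self, rng):
        x, y, z = rng.standard_normal((3, 4))
        np.testing.assert_allclose(opt.boosted_srand(2 * x, 2 * y, 2 * z),
                                   2 * opt.boosted_srand(x, y, z))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            opt.boosted_srand(np.ones(2), np.ones(3), np.ones(2))


class TestLevy:
    def test_sigma_at_three_halves(self):
        # independent evaluation via sympy's arbitrary-precision gamma
        import sympy as sp
        g = sp.Rational(3, 2)
        num = sp.gamma(1 + g) * sp.sin(sp.pi * g / 2)
        den = sp.gamma((1 + g) / 2) * g * 2 ** ((g - 1) / 2)
        expect = float(sp.N((num / den) ** (1 / g), 30))
        assert abs(opt.levy_sigma(1.5) - expect) < 1e-10

    def test_sigma_gamma_one_is_unity(self):
        assert opt.levy_sigma(1.0) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("g", [0.5, 1.0, 1.5, 2.0])
    def test_sigma_finite_positive(self, g):
        s = opt.levy_sigma(g)
        assert np.isfinite(s) and s > 0

    def test_sigma_domain(self):
        for g in (0.0, -1.0, 2.5):
            with pytest.raises(ValueError):
                opt.levy_sigma(g)

    def test_steps_are_heavy_tailed(self):
        from scipy.stats import kurtosis
        rng = np.random.default_rng(3)
        steps = opt.levy_flight(100_000, 1.5, rng)
        assert kurtosis(steps) > 10.0  # Gaussian excess kurtosis is 0


class TestUpdateEquations:
    def test_explore_perch_branch_returns_reference(self, scripted_rng):
        # q >= 0.5 and r1 = 0 collapses onto the boosted reference
        rng = scripted_rng(uniforms=[[0.9, 0.0, 0.3, 0.0, 0.0]])
        srand = np.array([0.3, -0.2])
        out = opt.explore_step(np.zeros(2), np.ones(2), np.zeros(2), srand,
                               np.full(2, -1.0), np.full(2, 1.0), rng)
        np.testing.assert_allclose(out, srand)

    def test_explore_prey_branch_with_zero_offset(self, scripted_rng):
        # q < 0.5 and r3 = 0 gives prey minus mean
        rng = scripted_rng(uniforms=[[0.2, 0.5, 0.5, 0.0, 0.7]])
        out = opt.explore_step(np.zeros(2), np.array([0.5, 0.5]),
                               np.array([0.2, 0.1]), np.zeros(2),
                               np.full(2, -1.0), np.full(2, 1.0), rng)
        np.testing.assert_allclose(out, [0.3, 0.4])

    def test_explore_respects_bounds(self):
        rng = np.random.default_rng(5)
        lb, ub = np.full(2, -1.0), np.full(2, 1.0)
        for _ in range(1000):
            pos = rng.uniform(lb, ub)
            prey = rng.uniform(lb, ub)
            mean = rng.uniform(lb, ub)
            srand = opt.boosted_srand(prey, mean, pos)
            out = opt.explore_step(pos, prey, mean, srand, lb, ub, rng)
            assert np.all(out >= lb) and np.all(out <= ub)

    def test_soft_besiege_at_prey_stays_at_prey_offset_zero(self, scripted_rng):
        prey = np.array([0.4, -0.1])
        out = opt.soft_besiege(prey.copy(), prey, 0.7,
                               scripted_rng(uniforms=[0.5]))  # Jp = 1
        np.testing.assert_allclose(out, 0.0)  # dS = 0 and |prey - S| = 0

    def test_soft_besiege_zero_energy_returns_delta(self, scripted_rng):
        pos, prey = np.array([1.0, 2.0]), np.array([0.0, 1.0])
        out = opt.soft_besiege(pos, prey, 0.0, scripted_rng(uniforms=[0.3]))
        np.testing.assert_allclose(out, prey - pos)

    def test_hard_besiege_cases(self):
        prey = np.array([1.0])
        np.testing.assert_allclose(opt.hard_besiege(np.zeros(1), prey, 0.0),
                                   prey)
        np.testing.assert_allclose(opt.hard_besiege(prey, prey, 0.4), prey)
        np.testing.assert_allclose(opt.hard_besiege(np.zeros(1), prey, 0.4),
                                   [0.6])

    def test_shepherd_step_reduces_to_best(self, scripted_rng):
        # attraction weight 0 and Levy numerator 0 leaves exactly S_best
        rng = scripted_rng(uniforms=[0.0], normals=[0.0, 1.0])
        prey = np.array([0.2, -0.3])
        out = opt.ssoa_step(np.ones(2), prey, 1.5, rng)
        np.testing.assert_allclose(out, prey)

    def test_dive_candidates_at_zero_energy(self, scripted_rng):
        prey = np.array([0.5, 0.5])
        rng = scripted_rng(uniforms=[0.3, 0.0], normals=[0.0, 1.0])
        u, v = opt.soft_besiege_dives(np.zeros(2), prey, 0.0, 1.5, rng)
        np.testing.assert_allclose(u, prey)
        np.testing.assert_allclose(v, prey)  # Q = 0 suppresses the Levy dive


class TestOptimize:
    @staticmethod
    def _sphere(x):
        return float(np.sum(x ** 2))

    def test_constant_objective_flat_history(self):
        cfg = opt.OptimizerConfig(n_hawks=5, n_iter=10, lb=-1, ub=1, dim=2,
                                  seed=0)
        res = opt.optimize(lambda x: 4.2, cfg)
        assert res.best_fitness == 4.2
        assert all(h["best_fitness"] == 4.2 for h in res.history)

    def test_seed_reproducibility(self):
        cfg = opt.OptimizerConfig(n_hawks=8, n_iter=25, lb=-5, ub=5, dim=3,
                                  seed=42)
        r1 = opt.optimize(self._sphere, cfg)
        r2 = opt.optimize(self._sphere, cfg)
        assert r1.history == r2.history
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_monotone_best_on_random_quadratics(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            center = rng.uniform(-1, 1, size=2)
            obj = lambda x, c=center: float(np.sum((x - c) ** 2))
            cfg = opt.OptimizerConfig(n_hawks=8, n_iter=20, lb=-2, ub=2,
                                      dim=2, seed=seed)
            hist = [h["best_fitness"] for h in opt.optimize(obj, cfg).history]
            assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_all_candidates_within_bounds(self):
        seen = []
        def obj(x):
            seen.append(x.copy())
            return self._sphere(x)
        cfg = opt.OptimizerConfig(n_hawks=10, n_iter=40, lb=-3, ub=3, dim=2,
                                  seed=9)
        opt.optimize(obj, cfg)
        pts = np.array(seen)
        assert np.all(pts >= -3) and np.all(pts <= 3)

    def test_energy_decays_with_iterations(self):
        # |Eg| <= 2 (1 - t/t*) because |Eg0| < 1 and C in (0, 1)
        cfg = opt.OptimizerConfig(n_hawks=5, n_iter=20, lb=-1, ub=1, dim=2,
                                  seed=2)
        t_max = cfg.n_iter
        for t in range(t_max):
            bound = 2.0 * (1 - t / t_max)
            for _ in range(100):
                eg = opt.escape_energy(np.random.default_rng(t).uniform(-1, 1),
                                       0.999, t, t_max)
                assert abs(eg) <= bound + 1e-12

    def test_maximization_sense(self):
        cfg = opt.OptimizerConfig(n_hawks=10, n_iter=50, lb=-2, ub=2, dim=1,
                                  seed=3, sense="maximize")
        res = opt.optimize(lambda x: -float(x[0] ** 2) + 1.0, cfg)
        assert res.best_fitness == pytest.approx(1.0, abs=1e-3)
        hist = [h["best_fitness"] for h in res.history]
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_nonfinite_candidates_rejected(self):
        def obj(x):
            return float("nan") if x[0] > 0 else self._sphere(x)
        cfg = opt.OptimizerConfig(n_hawks=6, n_iter=15, lb=-1, ub=1, dim=1,
                                  seed=4)
        res = opt.optimize(obj, cfg)
        assert np.isfinite(res.best_fitness)
        assert res.n_rejected_nonfinite > 0

    def test_warm_start_included(self):
        cfg = opt.OptimizerConfig(n_hawks=4, n_iter=1, lb=-1, ub=1, dim=2,
                                  seed=0)
        incumbent = np.array([[0.0, 0.0]])
        res = opt.optimize(self._sphere, cfg, init_positions=incumbent)
        assert res.best_fitness <= 1e-12

    def test_sphere_convergence(self):
        hits = 0
        for seed in range(20):
            cfg = opt.OptimizerConfig(n_hawks=30, n_iter=100, lb=-5, ub=5,
                                      dim=2, seed=seed)
            hits += opt.optimize(self._sphere, cfg).best_fitness <= 1e-3
        assert hits >= 18
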