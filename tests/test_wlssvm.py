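"""Weighted LS-SVM solver, PSO optimizer and the joint OSWLS-SVM search."""

import itertools

import numpy as np
import pytest

from teaspec.wlssvm import (
    PSOConfig,
    oswls_svm_train,
    pso_minimize,
    wlssvm_predict,
    wlssvm_solve,
)


class TestWLSSVMSolve:
    def test_vanishing_regularization_interpolates(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = 2.0 * X[:, 0] + 1.0
        model = wlssvm_solve(X, y, gamma=1e12, kernel="linear")
        assert np.max(np.abs(model.predict(X) - y)) <= 1e-6

    def test_equal_weights_linear_kernel_equals_ridge(self, rng):
        """LS-SVM with unit weights and a linear kernel minimizes
        ||y - Xw - b||^2 + ||w||^2/gamma, so it must match the closed-form
        ridge solution with an unpenalized intercept."""
        X = rng.normal(0, 1, (5, 2))
        y = rng.normal(0, 1, 5)
        gamma = 2.7
        model = wlssvm_solve(X, y, gamma, kernel="linear", weights=np.ones(5))
        A = np.block(
            [
                [X.T @ X + np.eye(2) / gamma, X.T @ np.ones((5, 1))],
                [np.ones((1, 5)) @ X, np.array([[5.0]])],
            ]
        )
        sol = np.linalg.solve(A, np.concatenate([X.T @ y, [y.sum()]]))
        probe = rng.normal(0, 1, (6, 2))
        expected = probe @ sol[:2] + sol[2]
        assert np.max(np.abs(model.predict(probe) - expected)) <= 1e-8 * max(
            1.0, np.max(np.abs(expected))
        )

    def test_kkt_residual_small(self, rng):
        X = rng.normal(0, 1, (15, 3))
        y = rng.normal(0, 1, 15)
        w = rng.uniform(0.2, 1.0, 15)
        model = wlssvm_solve(X, y, 5.0, kernel="rbf", sigma2=1.5, weights=w)
        from teaspec.wlssvm import _kernel_matrix

        omega = _kernel_matrix(X, X, "rbf", 1.5)
        eq1 = model.alpha.sum()
        eq2 = model.b + omega @ model.alpha + model.alpha / (5.0 * w) - y
        scale = np.linalg.norm(y)
        assert abs(eq1) < 1e-8 * scale
        assert np.linalg.norm(eq2) < 1e-8 * scale

    def test_tiny_weight_approaches_leave_one_out(self, rng):
        X = rng.normal(0, 1, (12, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(0, 0.1, 12)
        y[4] += 5.0  # gross outlier
        w = np.ones(12)
        w[4] = 1e-8
        down = wlssvm_solve(X, y, 10.0, kernel="rbf", sigma2=2.0, weights=w)
        keep = np.arange(12) != 4
        loo = wlssvm_solve(X[keep], y[keep], 10.0, kernel="rbf", sigma2=2.0)
        probe = rng.normal(0, 1, (6, 2))
        assert np.max(np.abs(down.predict(probe) - loo.predict(probe))) < 1e-4

    def test_predict_on_calibration_reproduces_interpolator(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 3.0, 5.0])
        model = wlssvm_solve(X, y, 1e12, kernel="linear")
        assert np.allclose(wlssvm_predict(model, X), y, atol=1e-6)

    def test_rbf_far_from_support_decays_to_bias(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        model = wlssvm_solve(X, y, 5.0, kernel="rbf", sigma2=1.0)
        far = np.full((1, 2), 1e3)
        assert model.predict(far)[0] == pytest.approx(model.b)

    def test_duplicate_probes_identical(self, rng):
        X = rng.normal(0, 1, (8, 2))
        model = wlssvm_solve(X, rng.normal(0, 1, 8), 3.0, kernel="rbf", sigma2=1.0)
        probe = np.tile(rng.normal(0, 1, (1, 2)), (3, 1))
        preds = model.predict(probe)
        assert preds[0] == preds[1] == preds[2]

    def test_invalid_parameters_rejected(self, rng):
        X = rng.normal(0, 1, (5, 2))
        y = rng.normal(0, 1, 5)
        with pytest.raises(ValueError, match="gamma"):
            wlssvm_solve(X, y, 0.0)
        with pytest.raises(ValueError, match="positive"):
            wlssvm_solve(X, y, 1.0, weights=np.array([1, 1, 0, 1, 1.0]))


def sphere(pos):
    return float(np.sum(pos**2))


class TestPSO:
    def test_sphere_benchmark(self):
        bounds = np.tile([[-5.0, 5.0]], (10, 1))
        _, best, _ = pso_minimize(sphere, bounds, PSOConfig(seed=0))
        assert best < 1e-2

    def test_single_cycle_returns_initial_best(self):
        config = PSOConfig(n_cycles=1, swarm_size=12, seed=3)
        bounds = np.tile([[-2.0, 2.0]], (4, 1))
        x, best, trace = pso_minimize(sphere, bounds, config)
        # recompute the initial swarm with the same seeded draw order
        rng = np.random.default_rng(3)
        init = -2.0 + rng.random((12, 4)) * 4.0
        vals = (init**2).sum(axis=1)
        assert best == pytest.approx(vals.min())
        assert trace.size == 1

    def test_trace_monotone_and_seeded(self):
        bounds = np.tile([[-5.0, 5.0]], (6, 1))
        _, best_a, trace_a = pso_minimize(sphere, bounds, PSOConfig(seed=11))
        _, best_b, trace_b = pso_minimize(sphere, bounds, PSOConfig(seed=11))
        assert np.array_equal(trace_a, trace_b)
        assert best_a == best_b
        assert np.all(np.diff(trace_a) <= 0)
        assert trace_a.size == 70

    def test_nan_objective_warns_and_continues(self):
        def bad(pos):
            return np.nan if pos[0] > 0 else float(pos[0] ** 2)

        with pytest.warns(UserWarning, match="NaN"):
            _, best, _ = pso_minimize(
                bad, np.array([[-1.0, 1.0]]), PSOConfig(n_cycles=5, swarm_size=8, seed=2)
            )
        assert np.isfinite(best)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            pso_minimize(sphere, np.array([[0.0, np.inf]]))


class TestOSWLSSVM:
    def test_matches_grid_search_on_clean_linear_data(self):
        """With clean data the jointly optimized model should reach (or
        beat) an equal-weights grid search over (gamma, sigma2) to within
        10 % monitoring RMSE."""
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, (20, 2))
        beta = np.array([2.0, -1.0])
        y = X @ beta + rng.normal(0, 0.02, 20)
        Xv = rng.uniform(-1, 1, (12, 2))
        yv = Xv @ beta + rng.normal(0, 0.02, 12)
        best = np.inf
        for lg, ls in itertools.product(np.linspace(-2, 6, 17), repeat=2):
            m = wlssvm_solve(X, y, 10.0**lg, kernel="rbf", sigma2=10.0**ls)
            best = min(best, float(np.sqrt(np.mean((yv - m.predict(Xv)) ** 2))))
        model = oswls_svm_train(X, y, Xv, yv, pso=PSOConfig(seed=2))
        assert model.validation_rmse <= 1.1 * best

    def test_outliers_get_downweighted(self):
        """Calibration outliers receive systematically smaller optimized
        weights than clean samples, across seeds."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1, 1, (30, 3))
            beta = np.array([1.5, -2.0, 0.5])
            y = X @ beta + rng.normal(0, 0.05, 30)
            outliers = np.array([3, 11, 22])
            y[outliers] += 10 * y.std()
            Xv = rng.uniform(-1, 1, (15, 3))
            yv = Xv @ beta + rng.normal(0, 0.05, 15)
            model = oswls_svm_train(
                X, y, Xv, yv, pso=PSOConfig(n_cycles=40, swarm_size=25, seed=seed + 50)
            )
            clean = np.setdiff1d(np.arange(30), outliers)
            hits += model.weights[outliers].mean() < model.weights[clean].mean()
        assert hits == 5

    def test_weights_within_bounds_and_trace_attached(self, rng):
        X = rng.normal(0, 1, (15, 2))
        y = rng.normal(0, 1, 15)
        model = oswls_svm_train(
            X, y, X[:5] + 0.1, y[:5], pso=PSOConfig(n_cycles=5, swarm_size=6, seed=0)
        )
        assert np.all(model.weights >= 1e-3) and np.all(model.weights <= 1.0)
        assert model.pso_trace.size == 5
        assert np.all(np.diff(model.pso_trace) <= 0)

    def test_empty_validation_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError, match="monitoring"):
            oswls_svm_train(X, rng.normal(0, 1, 10), np.empty((0, 2)), np.empty(0))
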