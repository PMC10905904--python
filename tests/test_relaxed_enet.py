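"""Relaxed elastic net: grid, selection, OLS limits, metrics."""

import numpy as np
import pytest

import ponzometa as pm
from ponzometa.relaxed_enet import _ridge_coefs, elastic_net_coefs


@pytest.fixture(scope="module")
def small_grid():
    return pm.HyperGrid(alphas=np.array([0.5, 1.0]),
                        lambdas=10.0 ** np.linspace(-3, 3, 13))


class TestStandardize:
    def test_hand_case_population_sd(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xs, _, _, _ = pm.standardize(X)
        np.testing.assert_allclose(Xs[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent_and_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(50, 4))
        y = rng.normal(size=50)
        Xs, ys, _, _ = pm.standardize(X, y)
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.var(axis=0), 1, atol=1e-12)
        assert abs(ys.mean()) < 1e-12 and abs(ys.var() - 1) < 1e-12
        Xs2, _, _, _ = pm.standardize(Xs)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)

    def test_zero_variance_column_named(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="flat_item"):
            pm.standardize(X, item_names=["flat_item", "ok"])


class TestHyperGrid:
    def test_default_grid_shape_and_spacing(self):
        g = pm.HyperGrid()
        assert len(g.alphas) == 10 and len(g.lambdas) == 100
        np.testing.assert_allclose(g.alphas, np.arange(1, 11) / 10)
        exps = np.log10(g.lambdas)
        assert exps[0] == pytest.approx(-3) and exps[-1] == pytest.approx(3)
        np.testing.assert_allclose(np.diff(exps), 2 / 33, atol=1e-12)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            pm.HyperGrid(alphas=np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            pm.HyperGrid(lambdas=np.array([-1.0]))


class TestGridSearch:
    def test_surface_size_is_grid_size(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        _, _, cv = pm.loocv_grid_search(X, y)
        assert cv.shape == (10, 100) and cv.size == 1000

    def test_signal_beats_intercept_only(self, small_grid):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = 2.0 * X[:, 1]
        _, _, cv = pm.loocv_grid_search(X, y, small_grid)
        assert cv.min() < y.var()

    def test_pure_noise_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        Xs, ys, _, _ = pm.standardize(X, y)
        _, best_lambda, _ = pm.loocv_grid_search(Xs, ys)
        assert best_lambda > 1.0

    def test_degenerate_response_errors(self, small_grid):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            pm.loocv_grid_search(X, np.ones(10), small_grid)


class TestRelaxedFit:
    def test_support_recovery_with_correct_sign(self, small_grid):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((120, 15))
        y = 0.8 * X[:, 3] + rng.normal(0, 0.1, 120)
        Xs, ys, _, _ = pm.standardize(X, y)
        fit = pm.relaxed_fit(Xs, ys, small_grid)
        assert "item_03" in fit.selected
        assert fit.importance["item_03"] > 0

    def test_permutation_invariance(self, small_grid):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 6))
        y = X[:, 2] - X[:, 4] + 0.2 * rng.standard_normal(25)
        Xs, ys, _, _ = pm.standardize(X, y)
        fit1 = pm.relaxed_fit(Xs, ys, small_grid)
        perm = rng.permutation(25)
        fit2 = pm.relaxed_fit(Xs[perm], ys[perm], small_grid)
        assert fit1.selected == fit2.selected
        for k in fit1.importance:
            assert fit1.importance[k] == pytest.approx(fit2.importance[k], abs=1e-8)

    def test_deterministic_bitwise(self, small_grid):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 5))
        y = X[:, 0] + rng.standard_normal(20)
        Xs, ys, _, _ = pm.standardize(X, y)
        a = pm.relaxed_fit(Xs, ys, small_grid)
        b = pm.relaxed_fit(Xs, ys, small_grid)
        np.testing.assert_array_equal(a.loocv_pred, b.loocv_pred)
        assert a.importance == b.importance

    def test_empty_selection_returns_intercept_model(self, small_grid):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 4))
        y = rng.standard_normal(15)
        Xs, ys, _, _ = pm.standardize(X, y)
        fit = pm.relaxed_fit(Xs, ys, small_grid)
        if not fit.selected:  # heavy shrinkage should empty the model
            assert fit.importance == {}
            assert len(fit.loocv_pred) == 15
        assert fit.cv_mode == "frozen"

    def test_nested_mode_runs(self, small_grid):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 5))
        y = X[:, 1] + 0.2 * rng.standard_normal(20)
        Xs, ys, _, _ = pm.standardize(X, y)
        fit = pm.relaxed_fit(Xs, ys, small_grid, cv_mode="nested")
        assert len(fit.loocv_pred) == 20


class TestOLSLimits:
    def test_tiny_penalty_elastic_net_approaches_ols(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 5))
        y = X @ np.array([1.0, -0.5, 0.3, 0.0, 0.7]) + 0.1 * rng.standard_normal(100)
        Xs, ys, _, _ = pm.standardize(X, y)
        w_enet = elastic_net_coefs(Xs, ys, alpha=0.1, lam=1e-6)
        w_ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(100), Xs]), ys, rcond=None)
        np.testing.assert_allclose(w_enet, w_ols[1:], atol=1e-3)

    def test_ridge_at_vanishing_lambda_equals_ols(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 4))
        y = X @ np.array([0.5, -1.0, 0.2, 0.0]) + 0.1 * rng.standard_normal(60)
        w_ridge, b = _ridge_coefs(X, y, 1e-12)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(60), X]), y,
                                   rcond=None)
        np.testing.assert_allclose(w_ridge, beta[1:], atol=1e-6)
        assert b == pytest.approx(beta[0], abs=1e-6)

    def test_doubling_lambda_never_grows_coefficients(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((80, 6))
        y = X[:, 0] - X[:, 3] + 0.3 * rng.standard_normal(80)
        Xs, ys, _, _ = pm.standardize(X, y)
        norms = [np.linalg.norm(elastic_net_coefs(Xs, ys, 0.5, lam))
                 for lam in (0.01, 0.02, 0.04, 0.08, 0.16, 0.32)]
        assert np.all(np.diff(norms) <= 1e-10)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rho, p, r2, rmse = pm.prediction_metrics(y, y)
        assert (rho, r2, rmse) == (1.0, 1.0, 0.0)

    def test_constant_prediction_null_model(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            rho, p, r2, rmse = pm.prediction_metrics(y, np.full(5, y.mean()))
        assert np.isnan(rho)
        assert r2 == pytest.approx(0.0)
        assert rmse == pytest.approx(y.std())  # population SD

    def test_hand_computed_five_pairs(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, p, r2, rmse = pm.prediction_metrics(y, yhat)
        assert rho == pytest.approx(0.8)         # 1 - 6*4/(5*24)
        assert r2 == pytest.approx(0.6)          # 1 - 4/10
        assert rmse == pytest.approx(np.sqrt(0.8))
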