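"""LASSO machinery: solver closed forms, CV, importance, refit."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from tsst_resilience.selection import (
    LassoConfig,
    augment_resample,
    coordinate_descent_lasso,
    lambda_path,
    refit_original,
    repeated_cv_select,
    select_predictors,
    variable_importance,
)


def _standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestAugmentResample:
    def test_rows_are_exact_copies(self, rng):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        aug, idx = augment_resample(df, 25, rng)
        assert len(aug) == 25
        originals = set(map(tuple, df.to_numpy()))
        assert set(map(tuple, aug.to_numpy())) <= originals

    def test_occupancy_matches_formula(self):
        """E[#distinct] = n(1-(1-1/n)^N) ~ 216 for n=248, N=500."""
        n, N = 248, 500
        expected = n * (1 - (1 - 1 / n) ** N)
        counts = [
            len(np.unique(augment_resample(np.arange(n), N, np.random.default_rng(i))[1]))
            for i in range(60)
        ]
        assert np.mean(counts) == pytest.approx(expected, abs=2.0)

    def test_deterministic_under_seed(self):
        df = pd.DataFrame({"a": np.arange(50.0)})
        a1, _ = augment_resample(df, 100, np.random.default_rng(7))
        a2, _ = augment_resample(df, 100, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a1, a2)

    def test_rejects_empty_and_shrinking(self, rng):
        with pytest.raises(ValueError):
            augment_resample(pd.DataFrame(), 10, rng)
        with pytest.raises(ValueError):
            augment_resample(pd.DataFrame({"a": [1, 2, 3]}), 2, rng)


class TestCoordinateDescent:
    def test_univariate_soft_threshold(self, rng):
        x = _standardized(rng, 300, 1)
        y = 0.8 * x[:, 0] + rng.standard_normal(300)
        y = y - y.mean()
        lam = 0.25
        rho = float(x[:, 0] @ y) / 300
        gram = float(x[:, 0] @ x[:, 0]) / 300
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0) / gram
        assert coordinate_descent_lasso(x, y, lam)[0] == pytest.approx(
            expected, abs=1e-8
        )

    def test_all_zero_at_lambda_max(self, rng):
        X = _standardized(rng, 200, 15)
        y = X[:, 0] + rng.standard_normal(200)
        y = y - y.mean()
        lam_max = np.max(np.abs(X.T @ y)) / 200
        assert np.all(coordinate_descent_lasso(X, y, lam_max) == 0.0)
        assert np.any(coordinate_descent_lasso(X, y, 0.95 * lam_max) != 0.0)

    def test_matches_ols_at_zero_penalty(self, rng):
        X = _standardized(rng, 150, 8)
        y = X @ rng.standard_normal(8) + 0.5 * rng.standard_normal(150)
        y = y - y.mean()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(coordinate_descent_lasso(X, y, 0.0) - ols).max() < 1e-6

    def test_matches_sklearn_oracle(self, rng):
        """Independent implementation of the same objective agrees."""
        X = _standardized(rng, 120, 12)
        beta = np.zeros(12)
        beta[:4] = [1.0, -0.7, 0.4, 0.2]
        y = X @ beta + rng.standard_normal(120)
        y = y - y.mean()
        for lam in (0.02, 0.1, 0.4):
            mine = coordinate_descent_lasso(X, y, lam)
            oracle = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=10**6)
            oracle.fit(X, y)
            assert np.abs(mine - oracle.coef_).max() < 1e-7

    def test_rejects_nonfinite(self, rng):
        X = _standardized(rng, 50, 3)
        y = np.zeros(50)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            coordinate_descent_lasso(X, y, 0.1)

    def test_path_continuity_in_lambda(self, rng):
        """Coefficient vector moves continuously along a fine grid."""
        X = _standardized(rng, 200, 10)
        y = X[:, 0] - 0.5 * X[:, 1] + rng.standard_normal(200)
        y = y - y.mean()
        coarse = lambda_path(X, y, LassoConfig(n_lambdas=100))
        fine = lambda_path(X, y, LassoConfig(n_lambdas=400))
        jump = lambda lams: np.abs(
            np.diff(
                np.array([coordinate_descent_lasso(X, y, lam) for lam in lams]),
                axis=0,
            )
        ).max()
        # refinement shrinks the largest adjacent-lambda jump
        assert jump(fine) < jump(coarse) < 0.2


class TestRepeatedCv:
    def test_pure_noise_prefers_large_lambda(self):
        cfg = LassoConfig(
            augmented_n=100, n_repeats=3, n_folds=5, n_lambdas=200, seed=0
        )
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            X = rng.standard_normal((100, 10))
            y = rng.standard_normal(100)
            cv = repeated_cv_select(X, y, cfg, rng=rng)
            hits += cv["lambda_min_index"] < 0.1 * len(cv["lambda_grid"])
        assert hits >= 16  # null model preferred in the upper grid decile

    def test_strong_signal_always_selected(self):
        cfg = LassoConfig(augmented_n=150, n_repeats=2, n_folds=5, n_lambdas=200)
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            X = rng.standard_normal((150, 8))
            y = 3.0 * X[:, 0] + np.sqrt(0.9) * rng.standard_normal(150)  # SNR 10
            cv = repeated_cv_select(X, y, cfg, rng=rng)
            beta = coordinate_descent_lasso(
                (X - X.mean(0)) / X.std(0, ddof=1), y - y.mean(), cv["lambda_min"]
            )
            assert beta[0] != 0.0

    def test_profile_minimum_is_global(self, rng):
        X = rng.standard_normal((120, 6))
        y = X[:, 0] + rng.standard_normal(120)
        cfg = LassoConfig(n_repeats=2, n_folds=5, n_lambdas=100)
        cv = repeated_cv_select(X, y, cfg, rng=rng)
        i = cv["lambda_min_index"]
        assert np.all(cv["cv_rmse_mean"][i] <= cv["cv_rmse_mean"] + 1e-12)


class TestImportanceAndRefit:
    def test_published_style_rescaling(self):
        imp = variable_importance([-3.865, 1.961, 0.0])
        assert imp[0] == 100.0
        assert imp[1] == pytest.approx(50.7, abs=0.05)
        assert imp[2] == 0.0

    def test_single_nonzero(self):
        assert variable_importance([0.0, -2.0, 0.0]) == pytest.approx([0, 100, 0])

    def test_scale_invariance_and_all_zero(self, rng):
        b = rng.standard_normal(6)
        assert variable_importance(b) == pytest.approx(variable_importance(-7.3 * b))
        assert np.all(variable_importance(np.zeros(4)) == 0.0)

    def test_exact_linear_relation_r2_one(self, rng):
        X = rng.standard_normal((100, 5))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + 3.0
        out = refit_original(X, y, 1e-8, LassoConfig())
        assert out["r2"] == pytest.approx(1.0, abs=1e-4)
        assert out["rmse"] < 1e-2

    def test_null_model_limit(self, rng):
        X = rng.standard_normal((300, 5))
        y = rng.standard_normal(300)
        out = refit_original(X, y, 10.0, LassoConfig())
        assert out["r2"] == pytest.approx(0.0, abs=1e-6)
        assert out["rmse"] == pytest.approx(np.std(y), rel=0.01)

    def test_back_transform_consistency(self, rng):
        """Original-scale coefficients reproduce standardized predictions."""
        X = rng.standard_normal((150, 6)) * np.array([1, 5, 0.2, 3, 1, 10])
        y = X[:, 0] - 0.3 * X[:, 1] + rng.standard_normal(150)
        out = refit_original(X, y, 0.05, LassoConfig())
        pred = X @ out["coefficients"] + out["intercept"]
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        pred_std = Xs @ out["coefficients_std_scale"] + y.mean()
        assert np.allclose(pred, pred_std, atol=1e-8)


class TestSelectPredictors:
    def test_deterministic_and_importance_normalized(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 12)), columns=[f"x{i}" for i in range(12)])
        y = 2 * X["x0"] - X["x1"] + rng.standard_normal(80)
        cfg = LassoConfig(augmented_n=120, n_repeats=2, n_folds=5, n_lambdas=150, seed=4)
        r1 = select_predictors(X, y, cfg)
        r2 = select_predictors(X, y, cfg)
        assert r1.lambda_min == r2.lambda_min
        assert r1.coefficients_at_min == r2.coefficients_at_min
        assert max(r1.importance.values()) == 100.0
        assert {"x0", "x1"} <= set(r1.selected)
        # importance 0 iff coefficient 0
        for name in r1.importance:
            assert (r1.importance[name] == 0.0) == (
                r1.coefficients_at_min[name] == 0.0
            )

    def test_cv_minimum_definitional(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        y = X["a"] + rng.standard_normal(60)
        cfg = LassoConfig(augmented_n=90, n_repeats=2, n_folds=5, n_lambdas=80, seed=2)
        rep = select_predictors(X, y, cfg)
        i = int(np.argmin(rep.cv_rmse_mean))
        assert rep.lambda_grid[i] == rep.lambda_min
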