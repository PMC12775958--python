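"""Transforms, PCA diagnostics, T-scores and the resilience index."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsst_resilience.composite import (
    TransformSpec,
    apply_transform,
    assess_normality,
    compute_composites,
    fit_pca_component,
    pca_suitability,
    resilience_index,
    to_t_scores,
)


def _data_with_exact_correlation(R, n=200, seed=0):
    """Sample matrix whose *sample* correlation equals R exactly."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, R.shape[0]))
    X = X - X.mean(axis=0)
    # whiten empirically, then color with chol(R)
    cov = X.T @ X / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    X = X @ np.linalg.cholesky(R).T
    return X


class TestAssessNormality:
    def test_symmetric_sample_has_zero_skewness(self, rng):
        half = rng.uniform(1, 5, 100)
        x = np.concatenate([half, -half])  # exact mirror image
        assert assess_normality(x)["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sample_flagged(self, rng):
        x = rng.exponential(size=248)
        res = assess_normality(x)
        assert res["transform_needed"]
        assert res["shapiro_p"] < 0.05

    def test_constant_input_degenerate(self):
        res = assess_normality(np.full(20, 3.0))
        assert res["degenerate"] and res["skewness"] == 0.0

    def test_normal_sample_flag_rate_near_alpha(self):
        flags = 0
        reps = 300
        for i in range(reps):
            x = np.random.default_rng(i).standard_normal(248)
            flags += assess_normality(x)["transform_needed"]
        # Shapiro-Wilk type-I rate ~5 %
        assert 0.02 < flags / reps < 0.09


class TestApplyTransform:
    def test_asinh_at_zero(self):
        out, _ = apply_transform([0.0, 1.0, -1.0], TransformSpec("x", "asinh_scaled"))
        assert out[0] == 0.0

    def test_asinh_symmetric_points(self):
        c = 2.5
        out, spec = apply_transform([-c, 0.0, c], TransformSpec("x", "asinh_scaled"))
        assert spec.scaling_constant == pytest.approx(c)
        assert out == pytest.approx([-np.arcsinh(1), 0.0, np.arcsinh(1)])
        assert np.arcsinh(1) == pytest.approx(np.log(1 + np.sqrt(2)))

    def test_log_powers_of_e(self):
        out, _ = apply_transform([1.0, np.e, np.e**2], TransformSpec("x", "log"))
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_log_rejects_nonpositive_with_guidance(self):
        with pytest.raises(ValueError, match="asinh"):
            apply_transform([1.0, -2.0], TransformSpec("x", "log"))


class TestPcaSuitability:
    def test_identity_correlation(self):
        X = _data_with_exact_correlation(np.eye(3), n=300)
        res = pca_suitability(X)
        assert res["determinant"] == pytest.approx(1.0, abs=1e-9)
        assert res["bartlett_chi2"] == pytest.approx(0.0, abs=1e-6)
        assert res["bartlett_df"] == 3

    def test_kmo_equicorrelation_hand_oracle(self):
        rho = 0.3
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, n=400)
        res = pca_suitability(X)
        # hand oracle: partial correlation of an equicorrelated triple is
        # rho/(1+rho); KMO = sum r^2 / (sum r^2 + sum q^2)
        q = rho / (1 + rho)
        kmo_oracle = (6 * rho**2) / (6 * rho**2 + 6 * q**2)
        assert res["kmo"] == pytest.approx(kmo_oracle, abs=1e-9)
        assert res["determinant"] == pytest.approx((1 - rho) ** 2 * (1 + 2 * rho), abs=1e-9)

    def test_rejects_singular(self):
        x = np.random.default_rng(0).standard_normal(100)
        X = np.column_stack([x, x, x])
        with pytest.raises(ValueError):
            pca_suitability(X)


class TestFitPcaComponent:
    def test_equicorrelation_closed_form(self):
        rho = 0.4
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, n=500)
        res = fit_pca_component(X)
        assert res.eigenvalues[0] == pytest.approx(1 + 2 * rho, abs=1e-9)
        assert res.eigenvalues.sum() == pytest.approx(3.0, abs=1e-9)
        expected_loading = np.sqrt((1 + 2 * rho) / 3)
        assert res.loadings == pytest.approx([expected_loading] * 3, abs=1e-9)
        assert res.variance_explained == pytest.approx((1 + 2 * rho) / 3, abs=1e-9)
        assert res.n_components_retained == 1

    def test_scores_unit_variance_and_positive_orientation(self):
        rho = 0.25
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, n=300, seed=3)
        res = fit_pca_component(X)
        assert res.scores.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        for j in range(3):
            assert np.corrcoef(X[:, j], res.scores)[0, 1] > 0

    def test_affine_rescaling_invariance(self):
        rho = 0.35
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, n=200, seed=4)
        res1 = fit_pca_component(X)
        X2 = X * np.array([3.0, 0.5, 10.0]) + np.array([-7.0, 2.0, 100.0])
        res2 = fit_pca_component(X2)
        assert np.allclose(res1.scores, res2.scores, atol=1e-9)


class TestTScoresAndIndex:
    def test_exact_mean_and_sd(self, rng):
        t = to_t_scores(rng.exponential(size=248))
        assert t.mean() == pytest.approx(50.0, abs=1e-9)
        assert t.std(ddof=1) == pytest.approx(10.0, abs=1e-9)

    def test_affine_map_of_standard_scores(self):
        z = np.array([-1.0, 0.0, 1.0])
        assert z.std(ddof=1) == 1.0
        assert to_t_scores(z) == pytest.approx([40.0, 50.0, 60.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            to_t_scores(np.ones(10))

    @pytest.mark.parametrize(
        "a,b,expected",
        [(50, 50, -50.0), (25, 100, -50.0), (74.62, 79.46, -77.00)],
    )
    def test_index_values(self, a, b, expected):
        assert resilience_index(a, b) == pytest.approx(expected, abs=5e-3)

    def test_index_symmetry_and_rejection(self):
        assert resilience_index(30, 70) == resilience_index(70, 30)
        with pytest.raises(ValueError):
            resilience_index(-1.0, 50.0)


class TestComputeComposites:
    def test_columns_and_standardization(self, small_composites):
        composites, report = small_composites
        for col in ("reactivity_t", "recovery_t"):
            assert composites[col].mean() == pytest.approx(50.0, abs=1e-9)
            assert composites[col].std(ddof=1) == pytest.approx(10.0, abs=1e-9)
        assert (composites["resilience_index"] < 0).all()

    def test_reactivity_recovery_positively_correlated(self, small_composites):
        composites, _ = small_composites
        r = np.corrcoef(composites["reactivity_t"], composites["recovery_t"])[0, 1]
        assert r > 0

    def test_orientation_rule(self, small_composites, full_cohort):
        # the sign flip guarantees a positive loading sum at any n ...
        _, report = small_composites
        assert report["reactivity"].loadings.sum() > 0
        assert report["recovery"].loadings.sum() > 0
        # ... and at the study sample size every loading is positive
        from tsst_resilience.features import compute_features

        feats = compute_features(full_cohort.physio)
        _, full_report = compute_composites(feats)
        assert np.all(full_report["reactivity"].loadings > 0)
        assert np.all(full_report["recovery"].loadings > 0)

    def test_default_correlation_in_design_band(self, full_cohort):
        """At the study sample size the generator lands r in [0.3, 0.6]."""
        from tsst_resilience.features import compute_features

        feats = compute_features(full_cohort.physio)
        composites, _ = compute_composites(feats)
        r = np.corrcoef(composites["reactivity_t"], composites["recovery_t"])[0, 1]
        assert 0.3 < r < 0.6
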