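import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from apcpls import DesignSpec, EffectSpec, appendix_fixture, build_design, fit_pls1, generate_cohort
from apcpls.pls import PLS1Regression

from conftest import random_regression


def ols_oracle(X, y):
    """Normal-equations OLS with intercept (full-rank designs only)."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def minimum_norm_oracle(X, y):
    """Moore-Penrose least squares on the centred problem."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.pinv(Xc) @ yc


class TestAgainstClosedForms:
    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=(50, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(size=50)
        fit = fit_pls1(x, y, 1)
        coef, intercept = fit.coefficients(1)
        expected = ols_oracle(x, y)
        assert coef[0] == pytest.approx(expected[1], abs=1e-10)
        assert intercept == pytest.approx(expected[0], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_components_equal_ols_on_full_rank(self, seed):
        X, y = random_regression(np.random.default_rng(seed), n=60, p=5)
        fit = fit_pls1(X, y, 5)
        coef, intercept = fit.coefficients(5)
        expected = ols_oracle(X, y)
        np.testing.assert_allclose(coef, expected[1:], atol=1e-8)
        assert intercept == pytest.approx(expected[0], abs=1e-8)
        np.testing.assert_allclose(fit.predict(X, 5), np.column_stack([np.ones(60), X]) @ expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_deficient_full_components_equal_minimum_norm(self, seed):
        rng = np.random.default_rng(seed)
        B = rng.normal(size=(30, 3))
        X = B @ rng.normal(size=(3, 6))  # 6 columns, rank 3
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        fit = fit_pls1(X, y, 6)
        assert fit.n_components_ == 3
        coef, _ = fit.coefficients(3)
        np.testing.assert_allclose(coef, minimum_norm_oracle(X, y), atol=1e-8)

    @pytest.mark.parametrize("scale", [False, True])
    @pytest.mark.parametrize("seed", range(3))
    def test_agreement_with_sklearn_pls(self, seed, scale):
        X, y = random_regression(np.random.default_rng(100 + seed), n=45, p=6)
        for h in (1, 2, 4):
            fit = fit_pls1(X, y, h, scale=scale)
            sk = PLSRegression(n_components=h, scale=scale).fit(X, y.reshape(-1, 1))
            coef, _ = fit.coefficients(h)
            np.testing.assert_allclose(coef, sk.coef_.ravel(), atol=1e-8)
            np.testing.assert_allclose(fit.predict(X, h), sk.predict(X).ravel(), atol=1e-8)


class TestWorkedExample:
    def test_weight_is_normalized_cross_product(self):
        fx = appendix_fixture()
        fit = fit_pls1(fx.X, fx.y, 1)
        np.testing.assert_allclose(fit.x_weights_[:, 0], np.asarray(fx.xty) / fx.singular_value, atol=1e-10)
        np.testing.assert_allclose(np.round(fit.x_weights_[:, 0], 3), [0.455, -0.360, -0.815])

    def test_score_regression_coefficient(self):
        fx = appendix_fixture()
        fit = fit_pls1(fx.X, fx.y, 1)
        assert fit.y_loadings_[0] == pytest.approx(0.026, abs=1e-12)

    def test_one_component_coefficients(self):
        fx = appendix_fixture()
        fit = fit_pls1(fx.X, fx.y, 1)
        coef, _ = fit.coefficients(1)
        np.testing.assert_allclose(np.round(coef, 3), [0.012, -0.009, -0.021])
        # the age and cohort coefficients sum to the period one (printed rounding)
        assert coef[0] + coef[2] == pytest.approx(coef[1], abs=1e-4)


class TestComponentStructure:
    @pytest.mark.parametrize("seed", range(4))
    def test_weights_unit_norm_scores_orthogonal(self, seed):
        X, y = random_regression(np.random.default_rng(seed), n=80, p=6)
        fit = fit_pls1(X, y, 4)
        np.testing.assert_allclose(np.linalg.norm(fit.x_weights_, axis=0), 1.0, atol=1e-12)
        G = fit.x_scores_.T @ fit.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    @pytest.mark.parametrize("seed", range(4))
    def test_covariance_with_outcome_decreasing(self, seed):
        X, y = random_regression(np.random.default_rng(50 + seed), n=80, p=6)
        fit = fit_pls1(X, y, 4)
        yc = y - y.mean()
        covs = np.abs(yc @ fit.x_scores_) / len(y)
        assert np.all(np.diff(covs) <= 1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_r2_nondecreasing_and_matches_ols(self, seed):
        X, y = random_regression(np.random.default_rng(200 + seed), n=60, p=5)
        fit = fit_pls1(X, y, 5)
        r2 = fit.explained_variance()
        assert np.all(np.diff(r2) >= -1e-12)
        assert r2[0] == pytest.approx(0.0, abs=1e-10)
        beta = ols_oracle(X, y)
        resid = y - np.column_stack([np.ones(60), X]) @ beta
        yc = y - y.mean()
        assert r2[-1] == pytest.approx(1.0 - resid @ resid / (yc @ yc), abs=1e-10)

    def test_exact_linear_one_component_r2_one(self, rng):
        x = rng.normal(size=(30, 1))
        y = 1.0 - 2.5 * x[:, 0]
        fit = fit_pls1(x, y, 1)
        assert fit.explained_variance()[1] == pytest.approx(1.0, abs=1e-12)

    def test_truncation_beyond_rank_warns(self, rng, caplog):
        y0 = rng.normal(size=20)
        X = np.outer(y0, [1.0, 2.0, 3.0])  # rank one
        y = y0 + 0.1 * rng.normal(size=20)
        with caplog.at_level("WARNING"):
            fit = fit_pls1(X, y, 3)
        assert fit.n_components_ == 1
        assert any("truncating" in r.message for r in caplog.records)

    def test_null_model(self, rng):
        X, y = random_regression(rng, n=30, p=3)
        fit = fit_pls1(X, y, 2)
        coef, intercept = fit.coefficients(0)
        np.testing.assert_array_equal(coef, 0.0)
        assert intercept == pytest.approx(y.mean())
        np.testing.assert_allclose(fit.predict(X, 0), y.mean())


class TestAPCConstraint:
    """On the rank-deficient APC design the coefficients stay orthogonal to
    the collinearity null direction — the implicit identification rule."""

    @pytest.mark.parametrize("h", [1, 2])
    @pytest.mark.parametrize("seed", range(5))
    def test_unscaled_year_units(self, seed, h):
        df = generate_cohort(EffectSpec(n_per_wave=250, seed=seed, confounder_effects={}))
        dm = build_design(df, DesignSpec(period_units="years"))
        fit = fit_pls1(dm, df["sbp"].to_numpy(), h)
        b, _ = fit.coefficients(h)
        assert abs(b[0] + b[2] - b[1]) <= 1e-10 * max(np.abs(b).max(), 1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_unscaled_wave_coding_carries_gap(self, seed):
        df = generate_cohort(EffectSpec(n_per_wave=250, seed=seed, confounder_effects={}))
        dm = build_design(df)  # 0/1 period column, waves 10 years apart
        fit = fit_pls1(dm, df["sbp"].to_numpy(), 2)
        b, _ = fit.coefficients(2)
        assert b[0] + b[2] == pytest.approx(10.0 * b[1], abs=1e-10 * max(np.abs(b).max(), 1.0))

    @pytest.mark.parametrize("h", [1, 2])
    def test_scaled_constraint_weighted_by_variances(self, h):
        df = generate_cohort(EffectSpec(n_per_wave=400, seed=3, confounder_effects={}))
        dm = build_design(df, DesignSpec(period_units="years"))
        fit = fit_pls1(dm, df["sbp"].to_numpy(), h, scale=True)
        b, _ = fit.coefficients(h)
        s = dm.values.std(axis=0, ddof=1)
        lhs = s[0] ** 2 * b[0] + s[2] ** 2 * b[2]
        assert lhs == pytest.approx(s[1] ** 2 * b[1], abs=1e-8 * max(abs(lhs), 1.0))


class TestValidationAndErrors:
    def test_zero_variance_outcome(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls1(X, np.ones(20), 1)

    def test_nonfinite_design(self, rng):
        X = rng.normal(size=(20, 3))
        X[3, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_pls1(X, rng.normal(size=20), 1)

    def test_h_out_of_range(self, rng):
        X, y = random_regression(rng, n=30, p=3)
        fit = fit_pls1(X, y, 2)
        with pytest.raises(ValueError, match="h must lie"):
            fit.coefficients(3)

    def test_predict_column_mismatch(self, rng):
        X, y = random_regression(rng, n=30, p=3)
        fit = fit_pls1(X, y, 2)
        with pytest.raises(ValueError, match="columns"):
            fit.predict(X[:, :2])

    def test_predict_design_name_mismatch(self, small_cohort):
        dm_lin = build_design(small_cohort)
        dm_spl = build_design(small_cohort, DesignSpec(spline=True))
        fit = fit_pls1(dm_lin, small_cohort["sbp"].to_numpy(), 2)
        with pytest.raises(ValueError, match="do not match"):
            fit.predict(dm_spl)

    def test_sklearn_get_set_params_roundtrip(self):
        est = PLS1Regression(n_components=3, scale=True)
        params = est.get_params()
        assert params == {"n_components": 3, "scale": True}
        est2 = PLS1Regression().set_params(**params)
        assert est2.get_params() == params
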