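import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonofit.glm_core import (
    DesignSpec,
    GLMFit,
    NestedTest,
    RankDeficientError,
    UndefinedDispersionError,
    dispersion,
    dispersion_test,
    f_test_nested,
    f_test_nested_ls,
    irls_poisson_log,
    ols_log,
    scaled_se,
    wls_log,
)
from clonofit.lq_model import build_lq_design
from clonofit.simulate import CurveSimSpec, simulate_curve_data

from conftest import fit_poisson_by_optimizer


def _intercept_spec(y, offset):
    return DesignSpec(
        design_matrix=np.ones((len(y), 1)),
        response=np.asarray(y, dtype=float),
        offset=np.asarray(offset, dtype=float),
    )


class TestIRLS:
    def test_saturated_single_plate(self):
        """One plate, intercept only: fitted mean equals the observation."""
        fit = irls_poisson_log(_intercept_spec([5], [np.log(10)]))
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(0.5), abs=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_intercept_fit_is_pooled_mean(self):
        """Two plates (3/10 and 9/30): ML gives the pooled mean 12/40."""
        fit = irls_poisson_log(_intercept_spec([3, 9], np.log([10.0, 30.0])))
        assert np.exp(fit.coefficients[0]) == pytest.approx(12 / 40, rel=1e-9)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_matches_direct_likelihood_maximization(self, seed):
        """IRLS solves the same ML problem as a generic Newton optimizer."""
        t = simulate_curve_data(CurveSimSpec(n_experiments=3, seed=seed))
        spec = build_lq_design(t)
        fit = irls_poisson_log(spec)
        ref = fit_poisson_by_optimizer(spec.design_matrix, spec.response, spec.offset)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-6)

    def test_matches_statsmodels_glm(self, curve_table):
        """Cross-check coefficients, covariance and deviance against an
        independent GLM implementation."""
        import statsmodels.api as sm

        spec = build_lq_design(curve_table)
        fit = irls_poisson_log(spec)
        ref = sm.GLM(
            spec.response,
            spec.design_matrix,
            family=sm.families.Poisson(),
            offset=spec.offset,
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.deviance, ref.deviance, rtol=1e-8)
        np.testing.assert_allclose(fit.pearson_chi2, ref.pearson_chi2, rtol=1e-8)
        np.testing.assert_allclose(
            fit.unscaled_covariance, ref.cov_params(), rtol=1e-5
        )

    def test_score_equations_hold_at_optimum(self, curve_table):
        spec = build_lq_design(curve_table)
        fit = irls_poisson_log(spec)
        score = spec.design_matrix.T @ (spec.response - fit.fitted_means)
        scale = spec.design_matrix.T @ fit.fitted_means
        assert np.all(np.abs(score / scale) < 1e-6)

    def test_reordering_records_leaves_coefficients_unchanged(self, curve_table):
        spec = build_lq_design(curve_table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(spec.n)
        shuffled = DesignSpec(
            design_matrix=spec.design_matrix[perm],
            response=spec.response[perm],
            offset=spec.offset[perm],
        )
        np.testing.assert_allclose(
            irls_poisson_log(spec).coefficients,
            irls_poisson_log(shuffled).coefficients,
            atol=1e-9,
        )

    @given(shift=st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_offset_shift_moves_intercept_exactly(self, shift):
        y = np.array([7.0, 11.0, 4.0, 9.0])
        base = _intercept_spec(y, np.log([20.0, 30.0, 10.0, 25.0]))
        shifted = _intercept_spec(y, base.offset + shift)
        b0 = irls_poisson_log(base).coefficients[0]
        b1 = irls_poisson_log(shifted).coefficients[0]
        assert b1 == pytest.approx(b0 - shift, abs=1e-7)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(RankDeficientError):
            DesignSpec(design_matrix=X, response=np.arange(4.0))

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            irls_poisson_log(_intercept_spec([-1, 2], [0.0, 0.0]))

    def test_nonconvergence_is_flagged_not_raised(self, curve_table):
        spec = build_lq_design(curve_table)
        fit = irls_poisson_log(spec, max_iter=1)
        assert not fit.converged


class TestDispersion:
    def test_dispersion_is_pearson_over_df(self, overdispersed_table):
        fit = irls_poisson_log(build_lq_design(overdispersed_table))
        assert dispersion(fit) == fit.pearson_chi2 / fit.df_residual
        assert dispersion(fit) > 1.0

    def test_saturated_fit_has_undefined_dispersion(self):
        fit = irls_poisson_log(_intercept_spec([5], [0.0]))
        with pytest.raises(UndefinedDispersionError):
            dispersion(fit)

    def test_chi2_test_values(self, curve_table):
        fit = irls_poisson_log(build_lq_design(curve_table))
        # dispersion exactly 1 at 38 d.f. -> p ~ 0.469 (chi-square upper tail)
        fit38 = GLMFit(
            coefficients=fit.coefficients,
            unscaled_covariance=fit.unscaled_covariance,
            deviance=fit.deviance,
            pearson_chi2=38.0,
            df_residual=38,
            fitted_means=fit.fitted_means,
            converged=True,
            iterations=1,
            spec=fit.spec,
        )
        assert dispersion_test(fit38) == pytest.approx(0.4695, abs=1e-4)
        fit38.pearson_chi2 = 4.34 * 38
        assert dispersion_test(fit38) < 0.05
        fit38.pearson_chi2 = 0.0
        assert dispersion_test(fit38) == 1.0

    def test_scaled_se_scaling_law(self, curve_table):
        fit = irls_poisson_log(build_lq_design(curve_table))
        unscaled = np.sqrt(np.diag(fit.unscaled_covariance))
        np.testing.assert_allclose(
            scaled_se(fit), unscaled * np.sqrt(dispersion(fit)), rtol=1e-12
        )
        # dispersion forced to 4 -> exactly 2x the unscaled errors
        fit.pearson_chi2 = 4.0 * fit.df_residual
        np.testing.assert_allclose(scaled_se(fit), 2.0 * unscaled, rtol=1e-12)

    def test_scaled_intervals_cover_better_on_overdispersed_data(self):
        """With lognormal replicate effects, dispersion-scaled 95% intervals
        for alpha cover the truth at least as often as unscaled ones."""
        from clonofit.lq_model import fit_lq

        alpha_true = 0.5
        cover_scaled = cover_unscaled = 0
        for seed in range(60):
            t = simulate_curve_data(
                CurveSimSpec(replicate_sd=0.25, n_experiments=6, seed=7000 + seed)
            )
            f = fit_lq(t, method="ml")
            se_unscaled = f.se_alpha / np.sqrt(f.dispersion)
            cover_scaled += abs(f.alpha - alpha_true) <= 1.96 * f.se_alpha
            cover_unscaled += abs(f.alpha - alpha_true) <= 1.96 * se_unscaled
        assert cover_scaled >= cover_unscaled
        assert cover_scaled >= 0.85 * 60  # near-nominal with scaling


class TestNestedFTest:
    def _fake(self, dev, chi2, df, y=None):
        y = np.zeros(3) if y is None else y
        spec = _intercept_spec(y, np.zeros(len(y)))
        return GLMFit(
            coefficients=np.zeros(1),
            unscaled_covariance=np.eye(1),
            deviance=dev,
            pearson_chi2=chi2,
            df_residual=df,
            fitted_means=np.ones(len(y)),
            converged=True,
            iterations=1,
            spec=spec,
        )

    def test_identical_models_rejected(self):
        a = self._fake(10.0, 12.0, 5)
        with pytest.raises(ValueError, match="nested"):
            f_test_nested(a, self._fake(10.0, 12.0, 5))

    def test_zero_deviance_drop_gives_f_zero_p_one(self):
        red = self._fake(10.0, 12.0, 6)
        full = self._fake(10.0, 10.0, 5)
        t = f_test_nested(red, full)
        assert t.statistic == 0.0
        assert t.p_value == 1.0
        assert t.df_num == 1

    def test_uses_full_model_dispersion(self):
        red = self._fake(30.0, 12.0, 7)
        full = self._fake(10.0, 10.0, 5)
        t = f_test_nested(red, full)
        assert t.dispersion_used == pytest.approx(10.0 / 5)
        assert t.statistic == pytest.approx((20.0 / 2) / 2.0)

    def test_different_response_rejected(self):
        red = self._fake(30.0, 12.0, 7, y=np.array([1.0, 2.0, 3.0]))
        full = self._fake(10.0, 10.0, 5, y=np.array([1.0, 2.0, 4.0]))
        with pytest.raises(ValueError, match="same response"):
            f_test_nested(red, full)


class TestLeastSquares:
    def test_perfect_line_has_zero_rss(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        spec = DesignSpec(design_matrix=X, response=np.array([1.0, 3.0]))
        fit = ols_log(spec)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)])
        y = rng.normal(size=20)
        fit = ols_log(DesignSpec(design_matrix=X, response=y))
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-10)

    def test_wls_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(43)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        w = rng.uniform(1, 50, size=15)
        fit = wls_log(DesignSpec(design_matrix=X, response=y, case_weights=w))
        ref = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-10)

    def test_intercept_only_ls_is_log_geometric_mean(self):
        """LS on log fractions averages the logs (geometric mean), while the
        unlogged arithmetic mean differs for unequal cell numbers."""
        k, n = np.array([3.0, 9.0]), np.array([10.0, 30.0])
        logf = np.log(k / n)
        fit = ols_log(
            DesignSpec(design_matrix=np.ones((2, 1)), response=logf)
        )
        assert fit.coefficients[0] == pytest.approx(logf.mean(), abs=1e-12)
        # equal per-plate fractions: geometric = arithmetic = 0.3
        assert np.exp(fit.coefficients[0]) == pytest.approx(0.3, rel=1e-12)

    def test_nonfinite_response_instructs_exclusion(self):
        spec = DesignSpec(
            design_matrix=np.ones((2, 1)), response=np.array([-np.inf, 0.0])
        )
        with pytest.raises(ValueError, match="zero-colony"):
            ols_log(spec)

    def test_ls_nested_f(self):
        rng = np.random.default_rng(44)
        x = rng.normal(size=30)
        y = 1.0 + 2.0 * x + rng.normal(size=30)
        red = ols_log(
            DesignSpec(design_matrix=np.ones((30, 1)), response=y)
        )
        full = ols_log(
            DesignSpec(design_matrix=np.column_stack([np.ones(30), x]), response=y)
        )
        t = f_test_nested_ls(red, full)
        assert t.df_num == 1 and t.df_den == 28
        # agreement with the textbook F formula
        expect = ((red.residual_ss - full.residual_ss) / 1) / (
            full.residual_ss / 28
        )
        assert t.statistic == pytest.approx(expect, rel=1e-12)
        assert t.p_value < 1e-6
        with pytest.raises(ValueError, match="nested"):
            f_test_nested_ls(full, full)
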