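import dataclasses

import numpy as np
import pytest

from exmort.glm_core import (
    COLUMNS,
    DegreesOfFreedomError,
    ModelSpec,
    SingularDesignError,
    apply_dispersion_policy,
    build_design,
    fit_quasipoisson,
    pearson_dispersion,
    predict_mean,
    prediction_rows,
)
from exmort.panel_io import MonthCoord, MonthlyCountSeries
from exmort.synthetic_data import SyntheticConfig, generate_counts
from oracles import plain_design, poisson_ml_oracle

from conftest import PRED_MONTHS, TRAIN_END, TRAIN_START


class TestBuildDesign:
    def test_training_window_shape(self, synthetic_series, default_spec):
        d = build_design(synthetic_series.series, default_spec)
        assert d.X.shape == (86, 15)  # 7 full years + Jan/Feb 2020
        assert d.coords[0] == TRAIN_START and d.coords[-1] == TRAIN_END
        assert list(d.columns) == list(COLUMNS)

    def test_january_rows_have_zero_month_block(self, synthetic_series, default_spec):
        d = build_design(synthetic_series.series, default_spec)
        for i, c in enumerate(d.coords):
            block = d.X[i, 2:13]
            if c.month == 1:
                assert np.all(block == 0)
            else:
                assert block.sum() == 1 and block[c.month - 2] == 1

    def test_lag_column_is_previous_month_rate(self, synthetic_series, default_spec):
        s = synthetic_series.series
        X, _ = prediction_rows(s, [MonthCoord(2020, 3)], 2013)
        assert X[0, 14] == s.u_at(MonthCoord(2020, 2))
        assert X[0, 13] == s.u_at(MonthCoord(2020, 3))

    def test_offset_is_log_population(self, synthetic_series, default_spec):
        d = build_design(synthetic_series.series, default_spec)
        np.testing.assert_allclose(
            d.offset, np.log(synthetic_series.series.population[:86])
        )

    def test_window_not_covered(self, synthetic_series, default_spec):
        spec = ModelSpec(training_window=(MonthCoord(2012, 1), TRAIN_END))
        with pytest.raises(ValueError, match="cover"):
            build_design(synthetic_series.series, spec)


class TestFit:
    def test_intercept_only_closed_form(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        fit = fit_quasipoisson(d)
        assert fit.coefficients[0] == pytest.approx(np.log(10.0), abs=1e-9)
        assert fit.converged

    def test_doubling_population_shifts_only_intercept(self, synthetic_series, default_spec):
        s = synthetic_series.series
        fit = fit_quasipoisson(build_design(s, default_spec), default_spec)
        s2 = dataclasses.replace(s, population=s.population * 2.0)
        fit2 = fit_quasipoisson(build_design(s2, default_spec), default_spec)
        assert fit2.coefficients[0] == pytest.approx(
            fit.coefficients[0] - np.log(2.0), abs=1e-7
        )
        np.testing.assert_allclose(
            fit2.coefficients[1:], fit.coefficients[1:], atol=1e-7
        )

    @pytest.mark.parametrize("seed,n,p", [(1, 24, 5), (2, 50, 6), (3, 30, 3)])
    def test_irls_matches_generic_ml_oracle(self, seed, n, p):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(0, 0.5, size=(n, p - 1))])
        offset = np.log(rng.uniform(50, 150, size=n))
        beta_true = rng.normal(0, 0.3, size=p)
        y = rng.poisson(np.exp(X @ beta_true + offset))
        fit = fit_quasipoisson(plain_design(X, y, offset))
        beta_oracle = poisson_ml_oracle(X, y, offset)
        np.testing.assert_allclose(fit.coefficients, beta_oracle, atol=1e-6)

    def test_score_identity_sum_mu_equals_sum_y(self, synthetic_series, default_spec):
        d = build_design(synthetic_series.series, default_spec)
        fit = fit_quasipoisson(d, default_spec)
        assert fit.mu_hat.sum() == pytest.approx(d.y.sum(), rel=1e-6)

    def test_deviance_path_monotone(self, synthetic_series, default_spec):
        d = build_design(synthetic_series.series, default_spec)
        fit = fit_quasipoisson(d, default_spec)
        path = np.array(fit.deviance_path)
        assert np.all(np.diff(path) <= 1e-9)

    def test_year_centering_invariance(self, synthetic_series, default_spec):
        """Shifting the year center moves the intercept, not the fit."""
        s = synthetic_series.series
        fit = fit_quasipoisson(build_design(s, default_spec), default_spec)
        shifted = ModelSpec(
            training_window=default_spec.training_window, year_center=2016
        )
        fit2 = fit_quasipoisson(build_design(s, shifted), shifted)
        c = 2016 - 2013  # year column shifted down by c
        assert fit2.coefficients[0] == pytest.approx(
            fit.coefficients[0] + c * fit.coefficients[1], abs=1e-7
        )
        np.testing.assert_allclose(fit2.mu_hat, fit.mu_hat, rtol=1e-8)

    def test_constant_unemployment_is_singular(self, default_spec):
        cfg = SyntheticConfig(
            seed=1,
            unemployment=dataclasses.replace(
                SyntheticConfig(seed=1).unemployment, innovation_sd=0.0
            ),
        )
        syn = generate_counts(cfg)
        with pytest.raises(SingularDesignError, match="unemployment"):
            fit_quasipoisson(build_design(syn.series, default_spec), default_spec)

    def test_matches_statsmodels_glm(self, synthetic_series, default_spec):
        sm = pytest.importorskip("statsmodels.api")
        d = build_design(synthetic_series.series, default_spec)
        fit = fit_quasipoisson(d, default_spec)
        ref = sm.GLM(
            d.y, d.X, family=sm.families.Poisson(), offset=d.offset
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        assert fit.dispersion_hat == pytest.approx(
            ref.pearson_chi2 / ref.df_resid, rel=1e-6
        )


class TestDispersion:
    def test_hand_computed_pearson_value(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        mu = np.full(4, 10.0)
        assert pearson_dispersion(d, mu) == pytest.approx(0.8 / 3)

    def test_zero_residuals_give_zero(self):
        d = plain_design(np.ones((3, 1)), [7, 7, 7])
        assert pearson_dispersion(d, np.full(3, 7.0)) == 0.0

    def test_dof_error(self):
        d = plain_design(np.ones((1, 1)), [4])
        with pytest.raises(DegreesOfFreedomError):
            pearson_dispersion(d, np.array([4.0]))

    def test_policy_below_one_falls_back_to_poisson(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        fit = fit_quasipoisson(d)
        assert fit.dispersion_hat == pytest.approx(0.8 / 3)
        assert fit.family_used == "poisson"
        assert fit.dispersion_used == 1.0

    def test_policy_boundary_and_scaling(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        base = fit_quasipoisson(d)
        at_one = apply_dispersion_policy(
            dataclasses.replace(base, dispersion_hat=1.0)
        )
        assert at_one.family_used == "quasipoisson"
        assert at_one.dispersion_used == 1.0
        over = apply_dispersion_policy(
            dataclasses.replace(base, dispersion_hat=1.8)
        )
        np.testing.assert_allclose(
            over.covariance, 1.8 * over.unscaled_covariance
        )

    def test_point_estimates_identical_across_families(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        fit = fit_quasipoisson(d)
        forced = apply_dispersion_policy(
            dataclasses.replace(fit, dispersion_hat=2.5)
        )
        np.testing.assert_array_equal(fit.coefficients, forced.coefficients)


class TestPredictMean:
    def test_zero_coefficients_return_population(self):
        d = plain_design(np.ones((4, 1)), [10, 12, 8, 10])
        fit = fit_quasipoisson(d)
        fit = dataclasses.replace(fit, coefficients=np.zeros(1))
        out = predict_mean(fit, np.ones((1, 1)), np.log([10_000.0]))
        assert out[0] == pytest.approx(10_000.0)

    def test_offset_log2_doubles_prediction(self, synthetic_series, default_spec):
        s = synthetic_series.series
        fit = fit_quasipoisson(build_design(s, default_spec), default_spec)
        X, off = prediction_rows(s, PRED_MONTHS, 2013)
        base = predict_mean(fit, X, off)
        doubled = predict_mean(fit, X, off + np.log(2.0))
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_layout_mismatch_rejected(self, synthetic_series, default_spec):
        fit = fit_quasipoisson(
            build_design(synthetic_series.series, default_spec), default_spec
        )
        with pytest.raises(ValueError, match="columns"):
            predict_mean(fit, np.ones((1, 3)), np.zeros(1))

    def test_held_out_mean_recovery_under_truth(self):
        """Point predictions track the true means of held-out months.

        Mean absolute relative error of y_tilde against true mu over the
        4 held-out months, averaged over 200 replicates, stays below 10%.
        """
        errs = []
        master = np.random.SeedSequence(314)
        spec = ModelSpec(training_window=(TRAIN_START, TRAIN_END))
        for child in master.spawn(200):
            syn = generate_counts(
                SyntheticConfig(seed=0), rng=np.random.default_rng(child)
            )
            fit = fit_quasipoisson(build_design(syn.series, spec), spec)
            X, off = prediction_rows(syn.series, PRED_MONTHS, 2013)
            pred = predict_mean(fit, X, off)
            true_mu = syn.true_mu[86:90]
            errs.append(np.mean(np.abs(pred - true_mu) / true_mu))
        assert np.mean(errs) < 0.10
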