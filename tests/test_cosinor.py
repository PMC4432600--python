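import numpy as np
import pandas as pd
import pytest
from scipy import stats

import circannual as ca
from circannual.cosinor import (MIN_P, TWO_PI, RankDeficiencyError, day_fractions)
from conftest import make_meta


class TestDayFraction:
    def test_july_15(self):
        assert ca.day_fraction("2003-07-15").t == pytest.approx(196 / 365, abs=1e-12)

    def test_january_15(self):
        assert ca.day_fraction("2003-01-15").t == pytest.approx(15 / 365, abs=1e-12)

    def test_leap_day(self):
        assert ca.day_fraction("2004-02-29").t == pytest.approx(60 / 366, abs=1e-12)

    def test_year_end_is_one(self):
        assert ca.day_fraction("2003-12-31").t == 1.0
        assert ca.day_fraction("2004-12-31").t == 1.0

    def test_unparseable_date(self):
        with pytest.raises(ValueError, match="unparseable"):
            ca.day_fraction("not-a-date")


class TestFitCosinorOLS:
    def test_noise_free_sinusoid_exact(self, ols_spec):
        t = (np.arange(12) + 1) / 12.0
        y = 2.0 + 1.0 * np.sin(TWO_PI * t)
        meta = make_meta(12)
        fit = ca.fit_cosinor(y, meta, ols_spec, t=t)
        assert fit.b_hat == pytest.approx(1.0, abs=1e-10)
        assert fit.c_hat == pytest.approx(0.0, abs=1e-10)
        assert fit.coef["intercept"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_response(self, ols_spec):
        meta = make_meta(20)
        fit = ca.fit_cosinor(np.full(20, 5.0), meta, ols_spec)
        assert fit.b_hat == pytest.approx(0.0, abs=1e-8)
        assert fit.c_hat == pytest.approx(0.0, abs=1e-8)

    def test_recovery_against_ols_oracle(self, ols_spec):
        rng = np.random.default_rng(5)
        meta = make_meta(400, seed=5)
        t = day_fractions(meta["date"])
        y = 7.0 + 0.5 * np.sin(TWO_PI * t) - 0.8 * np.cos(TWO_PI * t) \
            + rng.normal(0, 0.1, 400)
        fit = ca.fit_cosinor(y, meta, ols_spec, t=t)
        assert fit.b_hat == pytest.approx(0.5, abs=0.05)
        assert fit.c_hat == pytest.approx(-0.8, abs=0.05)
        # independent normal-equations solve
        X = np.column_stack([np.ones(400), np.sin(TWO_PI * t), np.cos(TWO_PI * t)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.b_hat == pytest.approx(beta[1], abs=1e-8)
        assert fit.c_hat == pytest.approx(beta[2], abs=1e-8)

    def test_too_few_observations(self, ols_spec):
        meta = make_meta(5)
        with pytest.raises(ValueError, match="at least 8"):
            ca.fit_cosinor(np.ones(5), meta, ols_spec)

    def test_non_finite_response(self, ols_spec):
        meta = make_meta(20)
        y = np.ones(20)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ca.fit_cosinor(y, meta, ols_spec)

    def test_rank_deficiency_reports_columns(self):
        meta = make_meta(30)
        meta["dup"] = meta["age"]
        spec = ca.ModelSpec(fixed_covariates=["age", "dup"])
        with pytest.raises(RankDeficiencyError) as err:
            ca.fit_cosinor(np.ones(30), meta, spec)
        assert "dup" in err.value.columns

    def test_bic_identity(self, ols_spec):
        meta = make_meta(50, seed=1)
        y = np.random.default_rng(1).normal(size=50)
        fit = ca.fit_cosinor(y, meta, ols_spec)
        assert fit.bic == pytest.approx(
            fit.n_params * np.log(fit.n_obs) - 2 * fit.loglik, abs=1e-10)


class TestFitNull:
    def test_constant_response(self, ols_spec):
        meta = make_meta(20)
        fit = ca.fit_null(np.full(20, 3.5), meta, ols_spec)
        assert fit.coef["intercept"] == pytest.approx(3.5, abs=1e-12)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-12)
        assert not fit.has_seasonal_terms

    def test_nested_loglik_ordering(self, ols_spec):
        rng = np.random.default_rng(2)
        meta = make_meta(60, seed=2)
        y = rng.normal(size=60)
        assert ca.fit_cosinor(y, meta, ols_spec).loglik >= \
            ca.fit_null(y, meta, ols_spec).loglik - 1e-10

    def test_rss_matches_normal_equations(self, ols_spec):
        rng = np.random.default_rng(3)
        meta = make_meta(80, seed=3)
        y = rng.normal(size=80)
        fit = ca.fit_null(y, meta, ols_spec)
        X = np.ones((80, 1))
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.rss == pytest.approx(rss, rel=1e-10)


class TestSeasonTest:
    def test_ols_f_matches_closed_form(self, ols_spec):
        rng = np.random.default_rng(4)
        meta = make_meta(100, seed=4)
        t = day_fractions(meta["date"])
        y = 1 + 0.3 * np.sin(TWO_PI * t) + rng.normal(0, 0.5, 100)
        fs = ca.fit_cosinor(y, meta, ols_spec, t=t)
        f0 = ca.fit_null(y, meta, ols_spec)
        res = ca.season_test(fs, f0)
        assert res.family == "F"
        n, p = 100, 3
        f_oracle = ((f0.rss - fs.rss) / 2) / (fs.rss / (n - p))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.p_value == pytest.approx(stats.f.sf(f_oracle, 2, n - p), rel=1e-10)

    def test_perfect_fit_returns_min_positive_p(self, ols_spec):
        meta = make_meta(24)
        t = (np.arange(24) + 1) / 24.0
        y = 1.0 + np.sin(TWO_PI * t)
        fs = ca.fit_cosinor(y, meta, ols_spec, t=t)
        f0 = ca.fit_null(y, meta, ols_spec)
        res = ca.season_test(fs, f0)
        assert res.p_value == MIN_P
        assert res.p_value > 0.0

    def test_mixed_lrt_family_and_df(self, small_study, mixed_spec):
        y = small_study.matrix.iloc[0].to_numpy()
        fs = ca.fit_cosinor(y, small_study.samples, mixed_spec)
        f0 = ca.fit_null(y, small_study.samples, mixed_spec)
        res = ca.season_test(fs, f0)
        assert res.family == "LRT_chisq"
        assert res.df == (2,)
        assert res.statistic == pytest.approx(2 * (fs.loglik - f0.loglik), abs=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 2), rel=1e-10)

    def test_non_nested_rejected(self, ols_spec):
        meta = make_meta(30)
        y = np.random.default_rng(0).normal(size=30)
        fs = ca.fit_cosinor(y, meta, ols_spec)
        with pytest.raises(ValueError, match="seasonal, null"):
            ca.season_test(fs, fs)


class TestMixedModelOracle:
    """The fast profiled-likelihood fitter must agree with statsmodels MixedLM."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_statsmodels_ml(self, seed, mixed_spec):
        import statsmodels.api as sm
        cfg = ca.SimulationConfig(n_subjects=25, visits_per_subject=4, n_features=1,
                                  frac_seasonal=1.0, acrophase_mode="uniform",
                                  subject_sd=0.6, residual_sd=0.4, seed=seed)
        study = ca.simulate_cohort(cfg)
        y = study.matrix.iloc[0].to_numpy()
        meta = study.samples
        fit = ca.fit_cosinor(y, meta, mixed_spec)

        t = day_fractions(meta["date"])
        frame = pd.DataFrame({
            "y": y, "age": meta["age"],
            "male": (meta["sex"] == "M").astype(float),
            "s": np.sin(TWO_PI * t), "c": np.cos(TWO_PI * t),
            "g": meta["subject_id"]})
        ref = sm.MixedLM.from_formula("y ~ age + male + s + c", groups="g",
                                      data=frame).fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fit.b_hat == pytest.approx(ref.params["s"], abs=1e-5)
        assert fit.c_hat == pytest.approx(ref.params["c"], abs=1e-5)
        assert fit.re_var["subject_id"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), abs=1e-4)

    def test_ols_reduction_one_visit_per_subject(self):
        # one observation per subject: the mixed path must collapse to OLS
        rng = np.random.default_rng(9)
        meta = make_meta(60, seed=9)  # distinct subject per sample
        y = rng.normal(size=60)
        mixed = ca.fit_cosinor(y, meta, ca.ModelSpec(random_intercepts=["subject_id"]))
        ols = ca.fit_cosinor(y, meta, ca.ModelSpec())
        assert mixed.b_hat == pytest.approx(ols.b_hat, abs=1e-8)
        assert mixed.c_hat == pytest.approx(ols.c_hat, abs=1e-8)
        assert mixed.coef["intercept"] == pytest.approx(ols.coef["intercept"], abs=1e-8)
        assert mixed.loglik == pytest.approx(ols.loglik, abs=1e-6)

    def test_multiple_random_intercepts_runs(self):
        cfg = ca.SimulationConfig(n_subjects=30, visits_per_subject=3, n_features=1,
                                  frac_seasonal=1.0, seed=3)
        study = ca.simulate_cohort(cfg)
        meta = study.samples.copy()
        meta["family_id"] = [f"F{int(s[1:]) // 2:04d}" for s in meta["subject_id"]]
        meta["zygosity"] = np.where(
            np.arange(len(meta)) % 2 == 0, "MZ", "DZ")
        spec = ca.ModelSpec(random_intercepts=["family_id", "zygosity"])
        y = study.matrix.iloc[0].to_numpy()
        fit = ca.fit_cosinor(y, meta, spec)
        assert np.isfinite(fit.loglik)
        assert set(fit.re_var) == {"family_id", "zygosity"}


class TestPhaseEquivariance:
    def test_shift_rotates_coefficients(self, ols_spec):
        rng = np.random.default_rng(6)
        meta = make_meta(120, seed=6)
        t = day_fractions(meta["date"])
        y = 0.7 * np.sin(TWO_PI * t) + 0.2 * np.cos(TWO_PI * t)
        base = ca.fit_cosinor(y, meta, ols_spec, t=t)
        k = 40
        shifted = ca.fit_cosinor(y, meta, ols_spec, t=np.mod(t + k / 365.0, 1.0))
        theta = TWO_PI * k / 365.0
        b_exp = base.b_hat * np.cos(theta) + base.c_hat * np.sin(theta)
        c_exp = -base.b_hat * np.sin(theta) + base.c_hat * np.cos(theta)
        assert shifted.b_hat == pytest.approx(b_exp, abs=1e-8)
        assert shifted.c_hat == pytest.approx(c_exp, abs=1e-8)


class TestWeeklyMeanExposure:
    def test_constant_series(self):
        series = ca.simulate_climate(("2014-01-01", "2014-12-31"), seed=0,
                                     temp_amplitude=0.0, noise_sd=0.0,
                                     mean_temp=4.5)
        assert ca.weekly_mean_exposure(series, "2014-06-10") == pytest.approx(4.5)

    def test_arithmetic_mean_of_window(self):
        dates = pd.date_range("2014-03-01", periods=7)
        data = pd.DataFrame({"date": [d.date().isoformat() for d in dates],
                             "tmean_c": np.arange(1.0, 8.0),
                             "sun_hours": np.zeros(7)})
        series = ca.ClimateSeries(data)
        assert ca.weekly_mean_exposure(series, "2014-03-08") == pytest.approx(4.0)

    def test_sinusoid_matches_direct_evaluation(self):
        series = ca.simulate_climate(("2014-01-01", "2014-12-31"), seed=0,
                                     noise_sd=0.0, sun_noise_sd=0.0)
        got = ca.weekly_mean_exposure(series, "2014-07-20")
        days = pd.date_range("2014-07-13", "2014-07-19")
        t = day_fractions([d.date() for d in days])
        expected = np.mean(10.0 + 8.0 * np.cos(TWO_PI * (t - 196 / 365)))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_days_error(self):
        series = ca.simulate_climate(("2014-06-01", "2014-06-30"), seed=0)
        with pytest.raises(ValueError, match="missing days"):
            ca.weekly_mean_exposure(series, "2014-06-03")


class TestClimatePredictor:
    def test_recovers_linear_temperature_effect(self, ols_spec):
        rng = np.random.default_rng(8)
        meta = make_meta(300, seed=8, start="2014-02-01", span_days=300)
        series = ca.simulate_climate(("2014-01-01", "2015-01-01"), seed=8)
        exposure = np.array([ca.weekly_mean_exposure(series, d) for d in meta["date"]])
        y = 3.0 + 0.12 * exposure + rng.normal(0, 0.2, 300)
        fit = ca.fit_climate_predictor(y, meta, exposure, ols_spec)
        # OLS oracle
        X = np.column_stack([np.ones(300), exposure])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef["exposure"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.coef["exposure"] == pytest.approx(0.12, abs=0.03)

    def test_constant_exposure_is_rank_deficient(self, ols_spec):
        meta = make_meta(30)
        with pytest.raises(RankDeficiencyError):
            ca.fit_climate_predictor(np.random.default_rng(0).normal(size=30),
                                     meta, np.full(30, 5.0), ols_spec)

    def test_cosinor_signal_visible_through_temperature(self, ols_spec):
        # expression driven by the annual cycle; temperature is in phase
        rng = np.random.default_rng(10)
        meta = make_meta(400, seed=10, start="2014-02-01", span_days=330)
        series = ca.simulate_climate(("2014-01-01", "2015-01-01"), seed=10, noise_sd=0.5)
        t = day_fractions(meta["date"])
        y = 6.0 - 0.6 * np.cos(TWO_PI * (t - 196 / 365)) + rng.normal(0, 0.4, 400)
        exposure = np.array([ca.weekly_mean_exposure(series, d) for d in meta["date"]])
        fit_temp = ca.fit_climate_predictor(y, meta, exposure, ols_spec)
        fit_0 = ca.fit_null(y, meta, ols_spec)
        assert fit_temp.loglik > fit_0.loglik + 10


class TestStudyScan:
    def test_columns_and_index(self, small_study, mixed_spec):
        res = ca.fit_study(small_study, mixed_spec)
        from circannual.cosinor import RESULT_COLUMNS
        assert list(res.columns) == RESULT_COLUMNS
        assert len(res) == small_study.n_features
        assert res["converged"].all()

    def test_amplitude_recovery_unbiased(self, ols_spec):
        # 500 features, n=400, one visit per subject (OLS path)
        cfg = ca.SimulationConfig(n_subjects=400, visits_per_subject=1,
                                  n_features=500, frac_seasonal=1.0,
                                  amplitude_range=(0.4, 0.4),
                                  acrophase_mode="uniform", subject_sd=0.0,
                                  residual_sd=0.5, seed=14)
        study = ca.simulate_cohort(cfg)
        res = ca.fit_study(study, ols_spec)
        amp = np.hypot(res["b_hat"], res["c_hat"])
        # MC error of the mean amplitude ~ 0.5/sqrt(400*500); allow small bias
        assert abs(amp.mean() - 0.4) < 0.01

    def test_null_p_uniform(self, ols_spec):
        cfg = ca.SimulationConfig(n_subjects=200, visits_per_subject=1,
                                  n_features=1000, frac_seasonal=0.0,
                                  subject_sd=0.0, residual_sd=0.5, seed=15)
        study = ca.simulate_cohort(cfg)
        res = ca.fit_study(study, ols_spec)
        ks = stats.kstest(res["p_season"], "uniform")
        assert ks.pvalue > 0.01
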