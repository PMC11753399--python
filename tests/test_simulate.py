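"""Ground-truth generator: determinism, calibration, generative arithmetic."""

import numpy as np
import pandas as pd
import pytest

from droughtnorms import hormones as hp
from droughtnorms.simulate import (
    SimulationConfig,
    _time_standardizer,
    simulate_gc_samples,
    simulate_individuals,
    simulate_mortality_table,
    simulate_rainfall,
    simulate_survival,
)


class TestRainfall:
    def test_deterministic_per_seed(self):
        cfg = SimulationConfig(seed=3)
        a, b = simulate_rainfall(cfg), simulate_rainfall(cfg)
        pd.testing.assert_series_equal(a, b)
        c = simulate_rainfall(SimulationConfig(seed=4))
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_zero_dry_mean_gives_dry_zeros(self):
        cfg = SimulationConfig(seed=3, dry_mean_mm=0.0)
        rain = simulate_rainfall(cfg)
        dry = rain[(rain.index.month < 5) | (rain.index.month > 11)]
        # wet-season bounds are month/day based; strictly-dry months only
        dry = dry[(dry.index.month != 11)]
        assert (dry == 0).all()

    def test_wet_season_mean_calibrated(self):
        cfg = SimulationConfig(
            seed=5, drought_year_multipliers={}, rain_start_year=2000, rain_end_year=2029
        )
        rain = simulate_rainfall(cfg)
        wet = rain[(rain.index.month >= 5) & (rain.index.month <= 11)]
        wet = wet[~((wet.index.month == 11) & (wet.index.day == 31))]
        assert wet.mean() == pytest.approx(cfg.wet_mean_mm, rel=0.05)

    def test_drought_year_scaled(self):
        cfg = SimulationConfig(seed=6, drought_year_multipliers={2009: 0.4})
        rain = simulate_rainfall(cfg)
        wet = rain[(rain.index.month >= 6) & (rain.index.month <= 10)]
        drought = wet[wet.index.year == 2009].mean()
        normal = wet[wet.index.year.isin([2008, 2010, 2011])].mean()
        assert drought < 0.65 * normal


class TestIndividuals:
    def test_zero_sds_give_zero_effects(self):
        cfg = SimulationConfig(seed=3, sd_random=(0, 0, 0, 0))
        _, truth = simulate_individuals(cfg)
        assert (truth[["b0", "bd", "br", "bdr"]].to_numpy() == 0).all()

    def test_truth_row_count(self):
        _, truth = simulate_individuals(SimulationConfig(seed=3, n_females=28))
        assert len(truth) == 28

    def test_empirical_covariance_matches_target(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.4
        cfg = SimulationConfig(seed=3, n_females=2000, corr_random=corr)
        _, truth = simulate_individuals(cfg)
        emp = np.cov(truth[["b0", "bd", "br", "bdr"]].to_numpy().T)
        target = cfg.random_effect_cov()
        assert np.abs(np.diag(emp) - np.diag(target)).max() < 0.1 * np.diag(target).max()
        assert emp[0, 1] == pytest.approx(target[0, 1], rel=0.25)

    def test_non_psd_correlation_errors(self):
        corr = np.array(
            [[1, 0.9, -0.9, 0], [0.9, 1, 0.9, 0], [-0.9, 0.9, 1, 0], [0, 0, 0, 1]]
        )
        with pytest.raises(ValueError, match="PSD"):
            SimulationConfig(seed=0, corr_random=corr).random_effect_cov()

    def test_slope_recomputable_from_effects(self):
        _, truth = simulate_individuals(SimulationConfig(seed=8))
        assert np.allclose(truth["true_slope_at_rain1"], truth["bd"] + truth["bdr"])


class TestGcSamples:
    def test_noiseless_linear_predictor(self, index_table):
        cfg = SimulationConfig(seed=3, sd_random=(0, 0, 0, 0), sigma_resid=0.0)
        females, truth = simulate_individuals(cfg)
        samples = simulate_gc_samples(cfg, females, truth, index_table)
        idx = index_table.set_index(pd.to_datetime(index_table["date"]))
        t_mean, t_sd = _time_standardizer()
        row = samples.iloc[17]
        rec = females[row["female_id"]]
        D = idx.loc[row["date"], "drought_risk"]
        R = idx.loc[row["date"], "expected_rainfall"]
        state = hp.merge_state(hp.assign_reproductive_state(rec, row["date"]))
        offset = {
            "not_pregnant": 0.0,
            "early_pregnancy": cfg.beta_early_pregnancy,
            "late_pregnancy": cfg.beta_late_pregnancy,
        }[state]
        eta = (
            cfg.beta0
            + cfg.beta_drought * D
            + cfg.beta_rain * R
            + cfg.beta_interaction * D * R
            + cfg.beta_time * (row["collection_time_min"] - t_mean) / t_sd
            + offset
        )
        # collection time is rounded to the minute after the draw
        assert np.log(row["gc_ng_per_g"]) == pytest.approx(eta, abs=2e-3)

    def test_all_zero_effects_give_unit_gc(self, index_table):
        cfg = SimulationConfig(
            seed=3,
            sd_random=(0, 0, 0, 0),
            sigma_resid=0.0,
            beta0=0.0,
            beta_drought=0.0,
            beta_rain=0.0,
            beta_interaction=0.0,
            beta_time=0.0,
            beta_early_pregnancy=0.0,
            beta_late_pregnancy=0.0,
        )
        females, truth = simulate_individuals(cfg)
        samples = simulate_gc_samples(cfg, females, truth, index_table)
        assert np.allclose(samples["gc_ng_per_g"], 1.0)

    def test_ols_recovers_doubled_drought_effect(self, index_table):
        import statsmodels.api as sm

        def ols_drought(beta_d, seed):
            cfg = SimulationConfig(
                seed=seed,
                n_females=60,
                samples_per_female_mean=60,
                sd_random=(0, 0, 0, 0),
                sigma_resid=0.05,
                beta_drought=beta_d,
            )
            females, truth = simulate_individuals(cfg)
            s = simulate_gc_samples(cfg, females, truth, index_table)
            idx = index_table.set_index(pd.to_datetime(index_table["date"]))
            D = idx.loc[s["date"], "drought_risk"].to_numpy()
            R = idx.loc[s["date"], "expected_rainfall"].to_numpy()
            t_mean, t_sd = _time_standardizer()
            t = (s["collection_time_min"].to_numpy() - t_mean) / t_sd
            X = sm.add_constant(np.column_stack([D, R, D * R, t]))
            return sm.OLS(np.log(s["gc_ng_per_g"]), X).fit().params.iloc[1]

        b1 = ols_drought(0.2, 11)
        b2 = ols_drought(0.4, 11)
        assert b2 / b1 == pytest.approx(2.0, rel=0.1)

    def test_planted_problems_counted(self, index_table):
        cfg = SimulationConfig(seed=3, n_gc_outliers=4, n_cv_failures=1)
        females, truth = simulate_individuals(cfg)
        samples = simulate_gc_samples(cfg, females, truth, index_table)
        assert (samples["assay_cv"] >= 0.20).sum() == 1


class TestSurvival:
    def test_null_coefficients_give_half_survival(self):
        cfg = SimulationConfig(
            seed=3, n_females=2000, gamma_slope=0, gamma_intercept=0, gamma_age=0, gamma_rank=0
        )
        _, truth = simulate_individuals(cfg)
        truth = simulate_survival(cfg, truth)
        assert truth["survived"].mean() == pytest.approx(0.5, abs=0.03)

    def test_extreme_slope_effect_separates(self):
        cfg = SimulationConfig(
            seed=3, n_females=200, gamma_slope=10, gamma_intercept=0, gamma_age=0, gamma_rank=0
        )
        _, truth = simulate_individuals(cfg)
        truth = simulate_survival(cfg, truth)
        surv = truth[truth["survived"] == 1]["true_slope_at_rain1"]
        dead = truth[truth["survived"] == 0]["true_slope_at_rain1"]
        assert surv.quantile(0.1) > dead.quantile(0.5)

    def test_deterministic(self):
        cfg = SimulationConfig(seed=3)
        _, truth = simulate_individuals(cfg)
        a = simulate_survival(cfg, truth)["survived"]
        b = simulate_survival(cfg, truth)["survived"]
        assert (a == b).all()


class TestMortalityTable:
    def test_baseline_rate_recovered(self):
        cfg = SimulationConfig(
            seed=3,
            severe_multiplier=1.0,
            yearly_exposure=20_000,
            baseline_death_rate=0.049,
        )
        t = simulate_mortality_table(cfg)
        assert t["deaths"].sum() / t["exposure"].sum() == pytest.approx(0.049, rel=0.05)

    def test_severe_multiplier_recovered(self):
        cfg = SimulationConfig(seed=3, yearly_exposure=50_000)
        t = simulate_mortality_table(cfg)
        severe = t[t["category"] == "severe_el_nino"]
        normal = t[t["category"] == "normal"]
        ratio = (severe["deaths"].sum() / severe["exposure"].sum()) / (
            normal["deaths"].sum() / normal["exposure"].sum()
        )
        assert ratio == pytest.approx(3.3, rel=0.1)

    def test_zero_exposure_zero_deaths(self):
        t = simulate_mortality_table(SimulationConfig(seed=3, yearly_exposure=0))
        assert (t["deaths"] == 0).all()

    def test_year_starts_may_15(self):
        t = simulate_mortality_table(SimulationConfig(seed=3))
        assert all(s.endswith("-05-15") for s in t["year_start"])
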