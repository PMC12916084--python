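import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lakegrowth as lg
from lakegrowth.synthetic import lake_mean_temps
from lakegrowth.thermal import gdd5_by_lake_year


class TestDailyTemps:
    def test_determinism(self, small_config):
        a = lg.simulate_daily_temps(small_config)
        b = lg.simulate_daily_temps(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_zero_gradient_identical_curves(self):
        cfg = lg.SimulationConfig(
            n_lakes=3, climate_gradient=(2000.0, 2000.0), day_noise_sd=0.0, seed=0
        )
        daily = lg.simulate_daily_temps(cfg)
        wide = daily.pivot(index="date", columns="lake_id", values="temp_c")
        assert np.allclose(wide.to_numpy(), wide.iloc[:, [0]].to_numpy())

    def test_complete_calendar_coverage(self, small_config, small_dataset):
        daily = small_dataset[0]
        dates = pd.to_datetime(daily["date"])
        for lake, grp in daily.groupby("lake_id"):
            d = pd.to_datetime(grp["date"])
            span = pd.date_range(d.min(), d.max(), freq="D")
            assert len(grp) == len(span)

    def test_gdd5_strictly_increasing_along_gradient(self):
        cfg = lg.SimulationConfig(n_lakes=6, day_noise_sd=0.0, seed=1)
        daily = lg.simulate_daily_temps(cfg)
        gdd = gdd5_by_lake_year(daily)
        annual = gdd.groupby("lake_id")["gdd5"].mean().sort_index()
        assert np.all(np.diff(annual.to_numpy()) > 0)

    def test_gradient_calibration_hits_target_gdd(self):
        # the inverted seasonal cycle should reproduce the requested
        # endpoint thermal energies within a few degree-days
        cfg = lg.SimulationConfig(n_lakes=2, climate_gradient=(1500.0, 3000.0), day_noise_sd=0.0, seed=0)
        daily = lg.simulate_daily_temps(cfg)
        gdd = gdd5_by_lake_year(daily)
        by_lake = gdd.groupby("lake_id")["gdd5"].mean()
        assert by_lake.iloc[0] == pytest.approx(1500.0, rel=0.02)
        assert by_lake.iloc[1] == pytest.approx(3000.0, rel=0.02)


class TestPopulations:
    @staticmethod
    def _t_table(values):
        return pd.DataFrame(
            {
                "lake_id": [f"lake_{i:03d}" for i in range(len(values))],
                "year": 2012,
                "t_scaled": values,
            }
        )

    def _noise_free_config(self, **kw):
        hp = lg.TrueHyperparams.default(1)
        hp.sigma_phi = {p: 0.0 for p in hp.sigma_phi}
        hp.sigma_tau = {p: 0.0 for p in hp.sigma_tau}
        hp.sigma_omega = {p: 0.0 for p in hp.sigma_omega}
        return lg.SimulationConfig(
            n_lakes=3, n_species=1, true_hyperparams=hp, longevity_lake_sd=0.0, seed=2, **kw
        )

    def test_noise_free_limit_is_linear_predictor(self):
        cfg = self._noise_free_config()
        hp = cfg.true_hyperparams
        t = self._t_table([-1.0, 0.0, 1.0])
        truth = lg.simulate_populations(cfg, t)
        expect = hp.gamma0["beta1"][0] + hp.gamma1["beta1"] * t["t_scaled"].to_numpy()
        assert np.allclose(truth.surveys["beta1"].to_numpy(), expect, atol=1e-12)

    def test_centred_covariate_gives_baseline(self):
        cfg = self._noise_free_config()
        truth = lg.simulate_populations(cfg, self._t_table([0.0, 0.0, 0.0]))
        assert np.allclose(
            truth.surveys["beta1"], cfg.true_hyperparams.gamma0["beta1"][0]
        )

    def test_juvenile_slope_recoverable_by_regression(self):
        cfg = lg.SimulationConfig(n_lakes=200, n_species=1, years_per_lake=1, seed=3)
        t_vals = np.random.default_rng(0).normal(size=200)
        truth = lg.simulate_populations(cfg, self._t_table(t_vals))
        res = stats.linregress(truth.surveys["t_scaled"], truth.surveys["beta1"])
        # a single species' realised slope is gamma1 plus its own tau draw
        true_slope = cfg.true_hyperparams.gamma1["beta1"] + truth.tau["beta1"].iloc[0]
        assert res.slope == pytest.approx(true_slope, abs=3 * res.stderr)

    def test_supports_and_max_age_floor(self, small_dataset):
        truth = small_dataset[3]
        s = truth.surveys
        assert (s["alpha"] >= 0).all()
        assert (s["beta1"] > 0).all()
        assert (s["amat"] >= 0.25).all()
        assert (s["max_age"] >= s["amat"] + 1.0).all()


class TestFish:
    def test_noise_free_lengths_equal_biphasic_mean(self):
        hp = lg.TrueHyperparams.default(1)
        hp.obs_sigma = np.array([1e-12])
        cfg = lg.SimulationConfig(n_lakes=2, n_species=1, true_hyperparams=hp, seed=4)
        t = pd.DataFrame(
            {"lake_id": ["lake_000", "lake_001"], "year": 2012, "t_scaled": [0.0, 0.5]}
        )
        truth = lg.simulate_populations(cfg, t)
        fish = lg.simulate_fish(truth, cfg)
        merged = fish.merge(truth.surveys, on=["species", "lake_id", "year"])
        mu = lg.biphasic_mean(
            merged["alpha"].to_numpy(),
            merged["beta1"].to_numpy(),
            merged["beta2"].to_numpy(),
            merged["amat"].to_numpy(),
            merged["age_yr"].to_numpy(),
        )
        assert np.allclose(merged["length_cm"], mu, rtol=1e-9)

    def test_age_95th_percentile_below_true_max(self, small_dataset):
        truth, fish = small_dataset[3], small_dataset[4]
        merged = fish.merge(
            truth.surveys[["species", "lake_id", "year", "max_age"]],
            on=["species", "lake_id", "year"],
        )
        assert (merged["age_yr"] <= merged["max_age"]).all()

    def test_log_residuals_normal(self):
        # the stated lognormal observation model at n ~ 1e4
        cfg = lg.SimulationConfig(
            n_lakes=10, n_species=1, years_per_lake=2, fish_per_survey=500, seed=6
        )
        _, _, _, truth, fish, _ = lg.simulate_dataset(cfg)
        merged = fish.merge(truth.surveys, on=["species", "lake_id", "year"])
        mu = lg.biphasic_mean(
            merged["alpha"].to_numpy(),
            merged["beta1"].to_numpy(),
            merged["beta2"].to_numpy(),
            merged["amat"].to_numpy(),
            merged["age_yr"].to_numpy(),
        )
        resid = np.log(merged["length_cm"].to_numpy()) - np.log(mu)
        z = resid / cfg.true_hyperparams.obs_sigma[0]
        # moment checks at Monte-Carlo resolution
        assert np.mean(z) == pytest.approx(0.0, abs=0.05)
        assert np.std(z) == pytest.approx(1.0, abs=0.05)
        assert stats.skew(z) == pytest.approx(0.0, abs=0.1)
        assert stats.kurtosis(z) == pytest.approx(0.0, abs=0.2)

    def test_invalid_obs_sigma_rejected(self):
        hp = lg.TrueHyperparams.default(1)
        hp.obs_sigma = np.array([-0.1])
        with pytest.raises(ValueError, match="obs_sigma"):
            lg.SimulationConfig(n_species=1, true_hyperparams=hp)


class TestMaskAges:
    def test_quota_of_zero_disallowed(self):
        with pytest.raises(ValueError, match="quota"):
            lg.SimulationConfig(aged_fraction_or_quota=0)

    def test_generous_quota_masks_nothing(self, small_dataset, small_config):
        from dataclasses import replace

        fish = small_dataset[4]
        cfg = replace(small_config, aged_fraction_or_quota=10_000)
        masked = lg.mask_ages(fish, cfg)
        assert masked["aged_flag"].all()

    def test_record_count_conserved_per_survey(self, small_dataset):
        fish, masked = small_dataset[4], small_dataset[5]
        key = ["species", "lake_id", "year"]
        before = fish.groupby(key).size()
        after = masked.groupby(key).size()
        pd.testing.assert_series_equal(before, after)

    def test_masked_rows_only_lose_age(self, small_dataset):
        fish, masked = small_dataset[4], small_dataset[5]
        assert masked.loc[~masked["aged_flag"], "age_yr"].isna().all()
        pd.testing.assert_series_equal(fish["length_cm"], masked["length_cm"])

    def test_fraction_quota_keeps_fraction_per_bin(self, small_dataset):
        from dataclasses import replace

        fish = small_dataset[4]
        cfg = replace(
            lg.SimulationConfig(seed=11), aged_fraction_or_quota=0.5, bin_width=2.0
        )
        masked = lg.mask_ages(fish, cfg)
        bins = np.floor(masked["length_cm"] / 2.0).astype(int)
        frac = masked.groupby(["species", "lake_id", "year", bins])["aged_flag"].mean()
        assert (frac >= 0.5 - 1e-9).all()


class TestDeterminism:
    def test_full_chain_reproducible(self, small_config):
        a = lg.simulate_dataset(small_config)
        b = lg.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a[4], b[4])
        pd.testing.assert_frame_equal(a[5], b[5])

    def test_seed_changes_output(self, small_config):
        from dataclasses import replace

        a = lg.simulate_dataset(small_config)[4]
        b = lg.simulate_dataset(replace(small_config, seed=99))[4]
        assert not a["length_cm"].equals(b["length_cm"])
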