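import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lakegrowth as lg
from lakegrowth.growth import GrowthData, GrowthState, linear_predictor

_LOG_2PI = np.log(2 * np.pi)


class TestBiphasicMean:
    def test_intercept_at_age_zero(self):
        p = lg.BiphasicParams(alpha=3.2, beta1=5.0, beta2=1.0, amat=2.5)
        assert p.mean(0.0) == pytest.approx(3.2)

    def test_continuity_at_change_point(self):
        p = lg.BiphasicParams(alpha=2.0, beta1=4.0, beta2=1.5, amat=3.7)
        eps = 1e-9
        assert p.mean(3.7 - eps) == pytest.approx(p.mean(3.7 + eps), abs=1e-7)
        assert p.mean(3.7) == pytest.approx(2.0 + 4.0 * 3.7, abs=1e-12)

    def test_northern_pike_juvenile_arithmetic(self):
        # largest reported intercept and fastest juvenile growth: a
        # one-year-old averages alpha + beta1
        assert lg.biphasic_mean(19.66, 11.80, 4.99, 5.36, 1.0) == pytest.approx(31.46)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            lg.biphasic_mean(1.0, 1.0, 1.0, 1.0, -0.5)

    @given(
        alpha=st.floats(0.0, 20.0),
        beta1=st.floats(0.1, 12.0),
        beta2=st.floats(0.0, 6.0),
        amat=st.floats(0.5, 8.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing_when_slopes_nonnegative(
        self, alpha, beta1, beta2, amat
    ):
        ages = np.linspace(0, 20, 100)
        y = lg.biphasic_mean(alpha, beta1, beta2, amat, ages)
        assert np.all(np.diff(y) >= -1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            lg.BiphasicParams(alpha=-1.0, beta1=1.0, beta2=1.0, amat=1.0)
        with pytest.raises(ValueError):
            lg.BiphasicParams(alpha=1.0, beta1=0.0, beta2=1.0, amat=1.0)


def _params_frame(**kw):
    base = dict(species="sp", lake_id="lk", year=2000, alpha=2.0, beta1=4.0, amat=3.0, beta2=1.5)
    base.update(kw)
    return pd.DataFrame([base])


def _fish_frame(ages, lengths, species="sp", lake="lk", year=2000):
    return pd.DataFrame(
        {
            "species": species,
            "lake_id": lake,
            "year": year,
            "length_cm": lengths,
            "age_yr": ages,
        }
    )


class TestLogLikelihood:
    def test_lengths_at_median_closed_form(self):
        params = _params_frame()
        ages = np.array([1.0, 2.0, 4.0, 6.0])
        mu = lg.biphasic_mean(2.0, 4.0, 1.5, 3.0, ages)
        rec = _fish_frame(ages, mu)
        sigma = 0.2
        got = lg.log_likelihood(rec, params, {"sp": sigma})
        expect = np.sum(-np.log(mu) - np.log(sigma) - 0.5 * _LOG_2PI)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_matches_scalar_lognormal_oracle(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0.5, 9, 10)
        mu = lg.biphasic_mean(2.0, 4.0, 1.5, 3.0, ages)
        lengths = mu * np.exp(rng.normal(0, 0.3, 10))
        rec = _fish_frame(ages, lengths)
        sigma = 0.3
        got = lg.log_likelihood(rec, _params_frame(), {"sp": sigma})
        oracle = 0.0
        for a, y in zip(ages, lengths):
            m = lg.biphasic_mean(2.0, 4.0, 1.5, 3.0, float(a))
            oracle += stats.lognorm.logpdf(y, s=sigma, scale=m)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_sigma_direction(self):
        # far from the data a wider scale raises the density; at the data
        # (median) it lowers it
        rec_far = _fish_frame([1.0], [60.0])
        rec_at = _fish_frame([1.0], [6.0])  # biphasic mean at age 1 is 6.0
        lo = {"sp": 0.2}
        hi = {"sp": 0.4}
        assert lg.log_likelihood(rec_far, _params_frame(), hi) > lg.log_likelihood(
            rec_far, _params_frame(), lo
        )
        assert lg.log_likelihood(rec_at, _params_frame(), hi) < lg.log_likelihood(
            rec_at, _params_frame(), lo
        )

    def test_nonpositive_length_rejected(self):
        rec = _fish_frame([1.0], [-3.0])
        with pytest.raises(ValueError, match="record"):
            lg.log_likelihood(rec, _params_frame(), {"sp": 0.2})

    def test_unmatched_survey_rejected(self):
        rec = _fish_frame([1.0], [5.0], lake="elsewhere")
        with pytest.raises(ValueError, match="survey"):
            lg.log_likelihood(rec, _params_frame(), {"sp": 0.2})


def _tiny_data(n_fish=20, n_lakes=2, seed=1):
    rng = np.random.default_rng(seed)
    lakes = [f"lk{i}" for i in range(n_lakes)]
    fish = pd.DataFrame(
        {
            "species": "sp",
            "lake_id": rng.choice(lakes, n_fish),
            "year": 2000,
            "length_cm": rng.uniform(5, 40, n_fish),
            "age_yr": rng.integers(1, 9, n_fish).astype(float),
        }
    )
    thermal = pd.DataFrame(
        {"lake_id": lakes, "year": 2000, "t_scaled": np.linspace(-1, 1, n_lakes)}
    )
    return GrowthData.from_frames(fish, thermal)


def _random_state(data, seed=2, scale=1.0):
    rng = np.random.default_rng(seed)
    J, L, S = data.n_species, data.n_lakes, data.n_surveys
    theta = np.column_stack(
        [
            rng.uniform(0.5, 5, S),
            rng.uniform(2, 8, S),
            rng.uniform(1, 6, S),
            rng.uniform(0.5, 3, S),
        ]
    )
    return GrowthState(
        theta=theta,
        gamma0=rng.uniform(1, 10, (J, 4)),
        gamma1=rng.normal(0, scale, 3),
        tau=rng.normal(0, 0.2, (J, 3)),
        omega=rng.normal(0, 0.3, (L, 4)),
        sig_phi=rng.uniform(0.1, 0.6, 4),
        sig_tau=rng.uniform(0.1, 0.4, 3),
        sig_omega=rng.uniform(0.1, 0.5, 4),
        sigma_obs=rng.uniform(0.1, 0.4, J),
    )


def _oracle_log_prior(state, gamma_prior_on="sd"):
    """Independently coded prior density sum using scipy distributions."""
    lp = 0.0
    for g in state.gamma0.ravel():
        lp += stats.uniform.logpdf(g, 0, 30)
    for g in state.gamma1:
        lp += stats.norm.logpdf(g)
    for i in range(3):
        lp += stats.norm.logpdf(state.tau[:, i], scale=state.sig_tau[i]).sum()
    for k in range(4):
        lp += stats.norm.logpdf(state.omega[:, k], scale=state.sig_omega[k]).sum()
    scales = np.concatenate(
        [state.sig_phi, state.sig_tau, state.sig_omega, state.sigma_obs]
    )
    for s in scales:
        if gamma_prior_on == "sd":
            lp += stats.gamma.logpdf(s, a=1.0, scale=1.0)
        else:
            lp += stats.gamma.logpdf(s**2, a=1.0, scale=1.0) + np.log(2 * s)
    return lp


def _oracle_log_posterior(state, data, gamma_prior_on="sd"):
    lp = _oracle_log_prior(state, gamma_prior_on)
    phi = linear_predictor(state, data)
    for k in range(4):
        lp += stats.norm.logpdf(
            state.theta[:, k], loc=phi[:, k], scale=state.sig_phi[k]
        ).sum()
    for i in range(data.n_fish):
        s = data.survey_of_fish[i]
        mu = lg.biphasic_mean(
            state.theta[s, 0],
            state.theta[s, 1],
            state.theta[s, 3],
            state.theta[s, 2],
            data.age[i],
        )
        sigma = state.sigma_obs[data.sp_of_fish[i]]
        lp += stats.lognorm.logpdf(np.exp(data.log_len[i]), s=sigma, scale=mu)
    return lp


class TestLogPrior:
    def test_out_of_bounds_baseline_is_minus_inf(self):
        data = _tiny_data()
        state = _random_state(data)
        state.gamma0[0, 0] = 31.0
        assert lg.log_prior(state) == -np.inf

    def test_standard_normal_slope_at_zero(self):
        data = _tiny_data()
        a = _random_state(data)
        b = a.copy()
        a.gamma1[:] = 0.0
        b.gamma1[:] = [0.0, 0.0, 1.0]
        # moving one slope from 0 to 1 costs exactly half a unit of log density
        assert lg.log_prior(a) - lg.log_prior(b) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("prior_on", ["sd", "variance"])
    def test_matches_density_sum_oracle(self, prior_on):
        data = _tiny_data()
        state = _random_state(data, seed=7)
        assert lg.log_prior(state, gamma_prior_on=prior_on) == pytest.approx(
            _oracle_log_prior(state, prior_on), abs=1e-10
        )


class TestLogPosterior:
    def test_matches_brute_force_oracle(self):
        data = _tiny_data(n_fish=20, n_lakes=2)
        state = _random_state(data, seed=3)
        assert lg.log_posterior(state, data) == pytest.approx(
            _oracle_log_posterior(state, data), abs=1e-8
        )

    def test_support_violation_is_minus_inf(self):
        data = _tiny_data()
        state = _random_state(data)
        state.theta[0, 1] = -0.5  # negative juvenile slope
        assert lg.log_posterior(state, data) == -np.inf

    def test_empty_lake_changes_value_only_through_its_priors(self):
        # same fish, one extra fishless lake: the difference is exactly the
        # new lake's random-effect prior terms plus its survey-free content
        import copy

        data = _tiny_data(n_fish=16, n_lakes=2, seed=5)
        state = _random_state(data, seed=6)
        lp_small = lg.log_posterior(state, data)

        data_big = copy.deepcopy(data)
        data_big.lake_names = data.lake_names + ["lk_empty"]
        state_big = state.copy()
        new_row = np.array([0.4, -0.2, 0.1, 0.3])
        state_big.omega = np.vstack([state.omega, new_row])
        lp_big = lg.log_posterior(state_big, data_big)
        extra_terms = stats.norm.logpdf(new_row, scale=state.sig_omega).sum()
        assert lp_big - lp_small == pytest.approx(extra_terms, abs=1e-8)


class TestSampler:
    def test_same_seed_identical_draws(self, small_dataset):
        _, thermal, _, _, fish, _ = small_dataset
        gd = GrowthData.from_frames(fish, thermal)
        cfg = lg.MCMCConfig(chains=2, iterations=200, burn_in=100, thin=2)
        a = lg.fit_growth_model(gd, cfg, seed=42)
        b = lg.fit_growth_model(gd, cfg, seed=42)
        assert np.array_equal(a.array, b.array)
        c = lg.fit_growth_model(gd, cfg, seed=43)
        assert not np.array_equal(a.array, c.array)

    def test_prior_only_run_recovers_slope_prior(self):
        # no fish at all: the marginal posterior of each global slope is its
        # standard normal prior
        fish = pd.DataFrame(
            {
                "species": pd.Series(dtype=str),
                "lake_id": pd.Series(dtype=str),
                "year": pd.Series(dtype=int),
                "length_cm": pd.Series(dtype=float),
                "age_yr": pd.Series(dtype=float),
            }
        )
        # surveys still exist (thermal rows), but carry no fish: build the
        # survey frame directly
        thermal = pd.DataFrame(
            {
                "lake_id": [f"lk{i}" for i in range(6)],
                "year": 2000,
                "t_scaled": np.linspace(-1.5, 1.5, 6),
            }
        )
        seed_fish = pd.DataFrame(
            {
                "species": "sp",
                "lake_id": thermal["lake_id"],
                "year": 2000,
                "length_cm": 10.0,
                "age_yr": 2.0,
            }
        )
        gd = GrowthData.from_frames(seed_fish, thermal)
        gd.age = np.empty(0)
        gd.log_len = np.empty(0)
        gd.survey_of_fish = np.empty(0, dtype=int)
        draws = lg.fit_growth_model(
            gd, lg.MCMCConfig(chains=2, iterations=4000, burn_in=1000, thin=1), seed=9
        )
        for p in ("beta1", "amat", "beta2"):
            x = draws.flat(f"gamma1[{p}]")
            assert x.mean() == pytest.approx(0.0, abs=0.15)
            assert x.std() == pytest.approx(1.0, abs=0.15)

    def test_retained_draw_count_matches_config(self, small_dataset):
        _, thermal, _, _, fish, _ = small_dataset
        gd = GrowthData.from_frames(fish, thermal)
        cfg = lg.MCMCConfig(chains=2, iterations=300, burn_in=100, thin=4)
        draws = lg.fit_growth_model(gd, cfg, seed=0)
        assert draws.n_draws == cfg.retained == 50
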