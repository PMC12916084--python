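"""Hierarchical Bayesian biphasic growth model.

Observed lengths are lognormal around the biphasic mean at the fish's age
with a per-species scale sigma_j.  Each survey (species x lake x year) has
its own biphasic parameters (alpha, beta1, amat, beta2) drawn around a
linear predictor: species baseline gamma0_p, plus — for beta1, amat and
beta2 — a temperature slope (global gamma1_p plus species deviation
tau_jp) on the z-scored thermal covariate, plus a lake random intercept
omega_lp on all four parameters.  Priors: Uniform(0, 30) on the species
baselines, Normal(0, 1) on the slopes, Gamma(1, 1) on the scale
hyperparameters (on SDs by default, switchable to variances).

The sampler is a blocked Gibbs scheme: conjugate draws for the
linear-Gaussian middle layer (gamma0, gamma1, tau, omega), adaptive
random-walk Metropolis for the survey-level parameters and all scale
parameters (adaptation during burn-in only, so detailed balance holds for
the retained draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .biphasic import PARAM_NAMES, SLOPE_PARAMS, THETA_HI, THETA_LO
from .mcmc import MCMCConfig, PosteriorDraws, sd_log_prior, truncnorm_draw

__all__ = [
    "GrowthData",
    "GrowthState",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "fit_growth_model",
]

_LOG_2PI = np.log(2.0 * np.pi)
GAMMA0_LO, GAMMA0_HI = 0.0, 30.0
_SLOPE_IDX = {p: i for i, p in enumerate(SLOPE_PARAMS)}
_PARAM_IDX = {p: i for i, p in enumerate(PARAM_NAMES)}


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------


@dataclass
class GrowthData:
    """Index-aligned arrays for the sampler.

    Surveys are the distinct species x lake x year combinations; fish
    arrays carry the survey index of each record.
    """

    species_names: list[str]
    lake_names: list[str]
    survey_frame: pd.DataFrame  # species, lake_id, year, t_scaled
    sp_of_survey: np.ndarray
    lake_of_survey: np.ndarray
    T: np.ndarray
    age: np.ndarray
    log_len: np.ndarray
    survey_of_fish: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_lakes(self) -> int:
        return len(self.lake_names)

    @property
    def n_surveys(self) -> int:
        return len(self.T)

    @property
    def n_fish(self) -> int:
        return len(self.age)

    @property
    def sp_of_fish(self) -> np.ndarray:
        return self.sp_of_survey[self.survey_of_fish]

    @classmethod
    def from_frames(cls, fish: pd.DataFrame, thermal: pd.DataFrame) -> "GrowthData":
        """Build from an aged fish table and a lake-year covariate table.

        ``fish`` needs species, lake_id, year, length_cm, age_yr (all
        aged); ``thermal`` needs lake_id, year, t_scaled.
        """
        if fish["age_yr"].isna().any():
            raise ValueError("all fish must be aged before fitting")
        if (fish["length_cm"] <= 0).any():
            bad = fish.loc[fish["length_cm"] <= 0].index[0]
            raise ValueError(f"nonpositive length at record {bad}")
        merged = fish.merge(thermal[["lake_id", "year", "t_scaled"]], on=["lake_id", "year"], how="left")
        if merged["t_scaled"].isna().any():
            missing = merged.loc[merged["t_scaled"].isna(), ["lake_id", "year"]].iloc[0]
            raise ValueError(
                f"no scaled temperature for lake {missing['lake_id']} year {missing['year']}"
            )
        surveys = (
            merged[["species", "lake_id", "year", "t_scaled"]]
            .drop_duplicates()
            .sort_values(["species", "lake_id", "year"])
            .reset_index(drop=True)
        )
        species_names = sorted(surveys["species"].unique())
        lake_names = sorted(surveys["lake_id"].unique())
        sp_map = {s: i for i, s in enumerate(species_names)}
        lake_map = {s: i for i, s in enumerate(lake_names)}
        sidx = surveys.reset_index().rename(columns={"index": "_survey"})
        sof = (
            merged.merge(
                sidx[["species", "lake_id", "year", "_survey"]],
                on=["species", "lake_id", "year"],
                how="left",
            )["_survey"]
            .to_numpy(dtype=int)
        )
        return cls(
            species_names=species_names,
            lake_names=lake_names,
            survey_frame=surveys,
            sp_of_survey=surveys["species"].map(sp_map).to_numpy(),
            lake_of_survey=surveys["lake_id"].map(lake_map).to_numpy(),
            T=surveys["t_scaled"].to_numpy(dtype=float),
            age=merged["age_yr"].to_numpy(dtype=float),
            log_len=np.log(merged["length_cm"].to_numpy(dtype=float)),
            survey_of_fish=sof,
        )


# --------------------------------------------------------------------------
# model state and densities
# --------------------------------------------------------------------------


@dataclass
class GrowthState:
    """One point in the model's parameter space.

    theta: (S, 4) survey-level (alpha, beta1, amat, beta2)
    gamma0: (J, 4); gamma1: (3,) slopes for (beta1, amat, beta2)
    tau: (J, 3); omega: (L, 4)
    sig_phi: (4,); sig_tau: (3,); sig_omega: (4,); sigma_obs: (J,)
    """

    theta: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    tau: np.ndarray
    omega: np.ndarray
    sig_phi: np.ndarray
    sig_tau: np.ndarray
    sig_omega: np.ndarray
    sigma_obs: np.ndarray

    def copy(self) -> "GrowthState":
        return GrowthState(
            *(getattr(self, f).copy() for f in (
                "theta", "gamma0", "gamma1", "tau", "omega",
                "sig_phi", "sig_tau", "sig_omega", "sigma_obs",
            ))
        )


def linear_predictor(state: GrowthState, data: GrowthData) -> np.ndarray:
    """phi (S, 4): the hierarchical mean of each survey-level parameter."""
    sp, lake, T = data.sp_of_survey, data.lake_of_survey, data.T
    phi = state.gamma0[sp, :] + state.omega[lake, :]
    for p in SLOPE_PARAMS:
        k = _PARAM_IDX[p]
        phi[:, k] += (state.gamma1[_SLOPE_IDX[p]] + state.tau[sp, _SLOPE_IDX[p]]) * T
    return phi


def _log_mu(theta: np.ndarray, age: np.ndarray, survey_of_fish: np.ndarray) -> np.ndarray:
    th = theta[survey_of_fish]
    juvenile = np.minimum(age, th[:, 2])
    adult = np.maximum(age - th[:, 2], 0.0)
    mu = th[:, 0] + th[:, 1] * juvenile + th[:, 3] * adult
    return np.log(np.maximum(mu, 1e-6))


@numba.njit(cache=False)
def _delta_loglik(theta_prop, age, logy, sof, gof, inv2s2, quad_cur, n_groups):
    """Fused per-fish pass: biphasic mean, log, squared residual, and the
    per-group log-likelihood change against the cached residuals."""
    n = age.shape[0]
    logmu_p = np.empty(n)
    quad_p = np.empty(n)
    dll = np.zeros(n_groups)
    for i in range(n):
        s = sof[i]
        a = age[i]
        am = theta_prop[s, 2]
        if a < am:
            mu = theta_prop[s, 0] + theta_prop[s, 1] * a
        else:
            mu = theta_prop[s, 0] + theta_prop[s, 1] * am + theta_prop[s, 3] * (a - am)
        if mu < 1e-6:
            mu = 1e-6
        lm = np.log(mu)
        q = logy[i] - lm
        q = q * q
        logmu_p[i] = lm
        quad_p[i] = q
        dll[gof[i]] -= (q - quad_cur[i]) * inv2s2[i]
    return logmu_p, quad_p, dll


def log_likelihood(
    records: pd.DataFrame,
    params_by_survey: pd.DataFrame,
    sigma_by_species: dict[str, float] | pd.Series,
) -> float:
    """Lognormal log-likelihood of observed lengths.

    ``records``: species, lake_id, year, length_cm, age_yr (aged).
    ``params_by_survey``: species, lake_id, year, alpha, beta1, amat, beta2.
    ``sigma_by_species``: lognormal scale per species.
    """
    merged = records.merge(params_by_survey, on=["species", "lake_id", "year"], how="left")
    if merged["alpha"].isna().any():
        bad = merged.loc[merged["alpha"].isna()].iloc[0]
        raise ValueError(
            f"no parameters for survey ({bad['species']}, {bad['lake_id']}, {bad['year']})"
        )
    y = merged["length_cm"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError(f"nonpositive length at record {int(np.argmax(y <= 0))}")
    a = merged["age_yr"].to_numpy(dtype=float)
    juvenile = np.minimum(a, merged["amat"].to_numpy(dtype=float))
    adult = np.maximum(a - merged["amat"].to_numpy(dtype=float), 0.0)
    mu = (
        merged["alpha"].to_numpy(dtype=float)
        + merged["beta1"].to_numpy(dtype=float) * juvenile
        + merged["beta2"].to_numpy(dtype=float) * adult
    )
    if np.any(mu <= 0):
        raise ValueError(
            f"nonpositive predicted mean at record {int(np.argmax(mu <= 0))}"
        )
    sigma = merged["species"].map(dict(sigma_by_species)).to_numpy(dtype=float)
    z = (np.log(y) - np.log(mu)) / sigma
    ll = -np.log(y) - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z
    return float(ll.sum())


def log_prior(state: GrowthState, gamma_prior_on: str = "sd") -> float:
    """Log prior of the hyperparameters.

    Uniform(0, 30) on every species baseline (-inf outside), standard
    normal on the global temperature slopes, centred normals on the random
    effects given their SDs, Gamma(1, 1) on every scale hyperparameter
    (placed on SDs by default, on variances when ``gamma_prior_on='variance'``).
    """
    if np.any(state.gamma0 <= GAMMA0_LO) or np.any(state.gamma0 >= GAMMA0_HI):
        return -np.inf
    kind = "gamma_sd" if gamma_prior_on == "sd" else "gamma_var"
    lp = -state.gamma0.size * np.log(GAMMA0_HI - GAMMA0_LO)
    lp += float(np.sum(-0.5 * _LOG_2PI - 0.5 * state.gamma1**2))
    for i, p in enumerate(SLOPE_PARAMS):
        lp += float(
            np.sum(stats.norm.logpdf(state.tau[:, i], scale=state.sig_tau[i]))
        )
    for k in range(4):
        lp += float(
            np.sum(stats.norm.logpdf(state.omega[:, k], scale=state.sig_omega[k]))
        )
    for s in (state.sig_phi, state.sig_tau, state.sig_omega, state.sigma_obs):
        term = sd_log_prior(s, kind)
        if not np.isfinite(term):
            return -np.inf
        lp += term
    return lp


def _theta_in_support(theta: np.ndarray) -> bool:
    return bool(np.all(theta >= THETA_LO) and np.all(theta <= THETA_HI))


def log_posterior(
    state: GrowthState, data: GrowthData, gamma_prior_on: str = "sd"
) -> float:
    """Log prior + middle-layer normal densities + lognormal likelihood.

    Survey-level parameters use a Normal(phi, sig_phi) density with a hard
    support indicator (alpha >= 0, beta1 > 0, amat in [0.25, 30]); -inf
    signals any support violation.
    """
    lp = log_prior(state, gamma_prior_on)
    if not np.isfinite(lp):
        return -np.inf
    if not _theta_in_support(state.theta):
        return -np.inf
    phi = linear_predictor(state, data)
    for k in range(4):
        lp += float(
            np.sum(
                stats.norm.logpdf(state.theta[:, k], loc=phi[:, k], scale=state.sig_phi[k])
            )
        )
    if data.n_fish:
        logmu = _log_mu(state.theta, data.age, data.survey_of_fish)
        sig = state.sigma_obs[data.sp_of_fish]
        z = (data.log_len - logmu) / sig
        lp += float(
            np.sum(-data.log_len - np.log(sig) - 0.5 * _LOG_2PI - 0.5 * z * z)
        )
    return lp


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------


def _initial_state(data: GrowthData, rng: np.random.Generator) -> GrowthState:
    """Crude per-species change-point least squares, jittered per chain so
    chains start overdispersed."""
    J, L, S = data.n_species, data.n_lakes, data.n_surveys
    gamma0 = np.empty((J, 4))
    sigma_obs = np.empty(J)
    length = np.exp(data.log_len)
    sp_fish = data.sp_of_fish if data.n_fish else np.empty(0, dtype=int)
    for j in range(J):
        mask = sp_fish == j
        if data.n_fish and mask.sum() >= 10:
            a = data.age[mask]
            y = length[mask]
            amat0 = float(np.clip(np.median(a), 1.0, 8.0))
            X = np.column_stack(
                [np.ones(mask.sum()), np.minimum(a, amat0), np.maximum(a - amat0, 0.0)]
            )
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            alpha0 = float(np.clip(coef[0], 0.05, 25.0))
            b1 = float(np.clip(coef[1], 0.1, 25.0))
            b2 = float(np.clip(coef[2], 0.05, 25.0))
            resid = np.log(y) - np.log(np.maximum(X @ coef, 1e-3))
            sigma_obs[j] = float(np.clip(np.std(resid), 0.02, 1.5))
        else:
            alpha0, b1, amat0, b2 = 2.0, 4.0, 3.0, 1.5
            sigma_obs[j] = 0.2
        gamma0[j] = [alpha0, b1, amat0, b2]
    gamma0 = gamma0 * np.exp(rng.normal(0.0, 0.05, size=gamma0.shape))
    gamma0 = np.clip(gamma0, 0.05, 29.0)
    theta = gamma0[data.sp_of_survey] * np.exp(rng.normal(0.0, 0.03, size=(S, 4)))
    theta = np.clip(theta, np.maximum(THETA_LO, 1e-3), np.minimum(THETA_HI, 29.5))
    return GrowthState(
        theta=theta,
        gamma0=gamma0,
        gamma1=rng.normal(0.0, 0.3, size=3),
        tau=np.zeros((J, 3)),
        omega=np.zeros((L, 4)),
        sig_phi=np.full(4, 0.3),
        sig_tau=np.full(3, 0.2),
        sig_omega=np.full(4, 0.3),
        sigma_obs=sigma_obs * np.exp(rng.normal(0.0, 0.05, size=J)),
    )


def _monitored_names(data: GrowthData) -> list[str]:
    names = []
    for p in PARAM_NAMES:
        for sp in data.species_names:
            names.append(f"gamma0[{p},{sp}]")
    for p in SLOPE_PARAMS:
        names.append(f"gamma1[{p}]")
    for p in SLOPE_PARAMS:
        for sp in data.species_names:
            names.append(f"tau[{p},{sp}]")
    for p in SLOPE_PARAMS:
        for sp in data.species_names:
            names.append(f"effect[{p},{sp}]")  # gamma1 + tau, per species
    for p in PARAM_NAMES:
        names.append(f"sig_phi[{p}]")
    for p in SLOPE_PARAMS:
        names.append(f"sig_tau[{p}]")
    for p in PARAM_NAMES:
        names.append(f"sig_omega[{p}]")
    for sp in data.species_names:
        names.append(f"sigma_obs[{sp}]")
    return names


def _snapshot(state: GrowthState, data: GrowthData) -> np.ndarray:
    vals = []
    for k in range(4):
        vals.extend(state.gamma0[:, k])
    vals.extend(state.gamma1)
    for i in range(3):
        vals.extend(state.tau[:, i])
    for i in range(3):
        vals.extend(state.gamma1[i] + state.tau[:, i])
    vals.extend(state.sig_phi)
    vals.extend(state.sig_tau)
    vals.extend(state.sig_omega)
    vals.extend(state.sigma_obs)
    return np.array(vals)


def _run_growth_chain(
    data: GrowthData,
    config: MCMCConfig,
    rng: np.random.Generator,
    gamma_prior_on: str,
) -> tuple[np.ndarray, dict]:
    S, J, L, N = data.n_surveys, data.n_species, data.n_lakes, data.n_fish
    sp_s, lake_s, T = data.sp_of_survey, data.lake_of_survey, data.T
    sof = data.survey_of_fish
    sp_f = data.sp_of_fish if N else np.empty(0, dtype=int)
    age, logy = data.age, data.log_len
    n_fish_per_survey = np.bincount(sof, minlength=S) if N else np.zeros(S)
    n_fish_per_species = np.bincount(sp_f, minlength=J) if N else np.zeros(J)
    n_surv_per_species = np.bincount(sp_s, minlength=J).astype(float)
    n_surv_per_lake = np.bincount(lake_s, minlength=L).astype(float)
    sumT2_per_species = np.bincount(sp_s, weights=T * T, minlength=J)

    state = _initial_state(data, rng)
    prior_kind = "gamma_sd" if gamma_prior_on == "sd" else "gamma_var"
    if prior_kind == "gamma_sd":
        def _prior_sd(s):
            return -s
    else:
        def _prior_sd(s):
            return -s * s + math.log(2.0 * s)

    # caches
    def recompute_fish(theta):
        if not N:
            return np.empty(0), np.empty(0)
        logmu = _log_mu(theta, age, sof)
        quad = (logy - logmu) ** 2
        return logmu, quad

    logmu, quad = recompute_fish(state.theta)
    inv2s2_f = (
        1.0 / (2.0 * state.sigma_obs[sp_f] ** 2) if N else np.empty(0)
    )

    # adaptive-covariance joint proposal for each survey's (alpha, beta1,
    # amat, beta2): the four parameters ride a sharp likelihood ridge, so
    # coordinatewise walks mix far too slowly
    th_mean = state.theta.copy()
    th_m2 = np.zeros((S, 4, 4))
    th_count = 1
    diag0 = 0.02 * (np.abs(state.theta) + 0.1)
    prop_chol = np.zeros((S, 4, 4))
    prop_chol[:, np.arange(4), np.arange(4)] = diag0
    lam = np.ones(S)
    n_theta_sweeps = 2
    step_shift_g0 = np.full((J, 4), 0.1)
    step_shift_om = np.full((L, 4), 0.1)
    step_shift_tau = np.full((J, 3), 0.1)
    step_shift_g1 = np.full(3, 0.1)
    zeros_S = np.zeros(S, dtype=int)
    zeros_F = np.zeros(N, dtype=int)
    step_ncp_phi = np.full(4, 0.3)
    step_ncp_om = np.full(4, 0.3)
    step_ncp_tau = np.full(3, 0.3)
    g0_mean = state.gamma0.copy()
    g0_m2 = np.zeros((J, 4, 4))
    g0_count = 1
    g0_chol = np.zeros((J, 4, 4))
    g0_chol[:, np.arange(4), np.arange(4)] = 0.05
    lam_g0 = np.ones(J)
    om_mean = state.omega.copy()
    om_m2 = np.zeros((L, 4, 4))
    om_count = 1
    om_chol = np.zeros((L, 4, 4))
    om_chol[:, np.arange(4), np.arange(4)] = 0.05
    lam_oml = np.ones(L)
    step_sig_phi = np.full(4, 0.3)
    step_sig_tau = np.full(3, 0.4)
    step_sig_omega = np.full(4, 0.3)
    step_sigma_obs = np.full(J, 0.1)
    adapt = 0.05
    target = 0.44

    n_keep = config.retained
    names = _monitored_names(data)
    out = np.empty((n_keep, len(names)))
    keep_i = 0
    acc_counts = np.zeros(4)
    acc_total = 0

    lo4, hi4 = THETA_LO, THETA_HI

    for it in range(config.iterations):
        adapting = it < config.burn_in
        phi = linear_predictor(state, data)

        # --- survey-level parameters: joint adaptive-covariance MH
        for _sweep in range(n_theta_sweeps):
            z = rng.standard_normal((S, 4))
            jump = lam[:, None] * np.einsum("sij,sj->si", prop_chol, z)
            prop = state.theta + jump
            ok = np.all((prop >= lo4) & (prop <= hi4), axis=1)
            theta_prop = np.where(ok[:, None], prop, state.theta)
            if N:
                logmu_p, quad_p, dll = _delta_loglik(
                    theta_prop, age, logy, sof, sof, inv2s2_f, quad, S
                )
            else:
                dll = np.zeros(S)
            dpr = -(
                ((theta_prop - phi) ** 2 - (state.theta - phi) ** 2)
                / (2.0 * state.sig_phi**2)
            ).sum(axis=1)
            log_acc = np.where(ok, dll + dpr, -np.inf)
            accept = np.log(rng.uniform(size=S)) < log_acc
            if np.any(accept):
                state.theta[accept] = prop[accept]
                if N:
                    f_acc = accept[sof]
                    logmu[f_acc] = logmu_p[f_acc]
                    quad[f_acc] = quad_p[f_acc]
            if adapting:
                lam *= np.exp(adapt * (accept.astype(float) - 0.25))
            acc_counts[0] += accept.mean()
        acc_total += 1

        if adapting:
            # running covariance of theta feeding the joint proposal
            th_count += 1
            d0 = state.theta - th_mean
            th_mean += d0 / th_count
            th_m2 += d0[:, :, None] * (state.theta - th_mean)[:, None, :]
            if th_count > 100 and it % 25 == 0:
                cov = th_m2 / (th_count - 1)
                cov[:, np.arange(4), np.arange(4)] += 1e-8 + 1e-4 * np.maximum(
                    cov[:, np.arange(4), np.arange(4)], 0
                )
                prop_chol = np.linalg.cholesky(cov) * (2.38 / 2.0)

        # --- conjugate middle layer
        inv_sp2 = 1.0 / state.sig_phi**2
        for k in range(4):
            ps = _PARAM_IDX_TO_SLOPE.get(k)
            slope_term = (
                (state.gamma1[ps] + state.tau[sp_s, ps]) * T if ps is not None else 0.0
            )
            # gamma0[j, k] | rest: flat within (0, 30)
            r = state.theta[:, k] - slope_term - state.omega[lake_s, k]
            prec = n_surv_per_species * inv_sp2[k]
            mean = np.bincount(sp_s, weights=r, minlength=J) * inv_sp2[k] / prec
            state.gamma0[:, k] = truncnorm_draw(
                rng, mean, np.sqrt(1.0 / prec), GAMMA0_LO, GAMMA0_HI
            )
            if ps is not None:
                # gamma1[ps] | rest: N(0,1) prior
                r = (
                    state.theta[:, k]
                    - state.gamma0[sp_s, k]
                    - state.tau[sp_s, ps] * T
                    - state.omega[lake_s, k]
                )
                prec1 = float(np.sum(T * T)) * inv_sp2[k] + 1.0
                mean1 = float(np.sum(T * r)) * inv_sp2[k] / prec1
                state.gamma1[ps] = mean1 + rng.standard_normal() / np.sqrt(prec1)
                # tau[j, ps] | rest: N(0, sig_tau) prior
                r = (
                    state.theta[:, k]
                    - state.gamma0[sp_s, k]
                    - state.gamma1[ps] * T
                    - state.omega[lake_s, k]
                )
                prec_t = sumT2_per_species * inv_sp2[k] + 1.0 / state.sig_tau[ps] ** 2
                mean_t = (
                    np.bincount(sp_s, weights=T * r, minlength=J) * inv_sp2[k] / prec_t
                )
                state.tau[:, ps] = mean_t + rng.standard_normal(J) / np.sqrt(prec_t)
                slope_term = (state.gamma1[ps] + state.tau[sp_s, ps]) * T
            # omega[l, k] | rest: N(0, sig_omega) prior
            r = state.theta[:, k] - state.gamma0[sp_s, k] - slope_term
            prec_o = n_surv_per_lake * inv_sp2[k] + 1.0 / state.sig_omega[k] ** 2
            mean_o = np.bincount(lake_s, weights=r, minlength=L) * inv_sp2[k] / prec_o
            state.omega[:, k] = mean_o + rng.standard_normal(L) / np.sqrt(prec_o)

        # --- group-shift moves: a hyperparameter and every survey-level
        # parameter under it move together.  The middle-layer prior is
        # invariant under the shift, so acceptance is driven by the
        # likelihood; this is what mixes the collective directions that
        # coordinatewise updates cannot reach when shrinkage is strong.
        def shift_update(k, g_of_s, g_of_f, n_groups, mult, step, dprior_fn, apply_fn):
            delta = step * rng.standard_normal(n_groups)
            shift_s = delta[g_of_s] * mult
            col = state.theta[:, k] + shift_s
            bad = (col < lo4[k]) | (col > hi4[k])
            bad_g = np.bincount(g_of_s, weights=bad.astype(float), minlength=n_groups) > 0
            theta_prop = state.theta.copy()
            theta_prop[:, k] = np.where(bad, state.theta[:, k], col)
            if N:
                logmu_p, quad_p, dll = _delta_loglik(
                    theta_prop, age, logy, sof, g_of_f, inv2s2_f, quad, n_groups
                )
            else:
                dll = np.zeros(n_groups)
            log_acc = np.where(bad_g, -np.inf, dll + dprior_fn(delta))
            accept = np.log(rng.uniform(size=n_groups)) < log_acc
            if np.any(accept):
                acc_s = accept[g_of_s]
                state.theta[acc_s, k] = col[acc_s]
                if N:
                    f_acc = accept[g_of_f]
                    logmu[f_acc] = logmu_p[f_acc]
                    quad[f_acc] = quad_p[f_acc]
                apply_fn(accept, delta)
            return accept.astype(float)

        sp_f_idx = sp_f if N else np.empty(0, dtype=int)
        lake_f = lake_s[sof] if N else np.empty(0, dtype=int)
        ones_T = np.ones(S)

        # --- species-level joint shift: move gamma0[j, :] and every theta
        # of species j together with a covariance-adapted 4-d jump, to cross
        # the alpha/beta1/amat ridge that single-coordinate shifts cannot
        z4 = rng.standard_normal((J, 4))
        jump4 = lam_g0[:, None] * np.einsum("jik,jk->ji", g0_chol, z4)
        g0_prop = state.gamma0 + jump4
        ok_g0 = np.all((g0_prop > GAMMA0_LO) & (g0_prop < GAMMA0_HI), axis=1)
        theta_prop = state.theta + jump4[sp_s]
        bad_s = np.any((theta_prop < lo4) | (theta_prop > hi4), axis=1)
        ok_g0 &= ~(np.bincount(sp_s, weights=bad_s.astype(float), minlength=J) > 0)
        theta_prop = np.where(ok_g0[sp_s, None], theta_prop, state.theta)
        if N:
            logmu_p, quad_p, dll4 = _delta_loglik(
                theta_prop, age, logy, sof, sp_f_idx, inv2s2_f, quad, J
            )
        else:
            dll4 = np.zeros(J)
        accept4 = np.log(rng.uniform(size=J)) < np.where(ok_g0, dll4, -np.inf)
        if np.any(accept4):
            acc_s = accept4[sp_s]
            state.theta[acc_s] = theta_prop[acc_s]
            state.gamma0[accept4] += jump4[accept4]
            if N:
                f_acc = accept4[sp_f_idx]
                logmu[f_acc] = logmu_p[f_acc]
                quad[f_acc] = quad_p[f_acc]
        if adapting:
            lam_g0 *= np.exp(adapt * (accept4.astype(float) - 0.25))
            g0_count += 1
            d0 = state.gamma0 - g0_mean
            g0_mean += d0 / g0_count
            g0_m2 += d0[:, :, None] * (state.gamma0 - g0_mean)[:, None, :]
            if g0_count > 100 and it % 25 == 0:
                cov = g0_m2 / (g0_count - 1)
                cov[:, np.arange(4), np.arange(4)] += 1e-8
                g0_chol = np.linalg.cholesky(cov) * (2.38 / 2.0)
        for k in range(4):
            # species baseline + its thetas (flat prior inside the bounds)
            def dp_g0(delta, k=k):
                new = state.gamma0[:, k] + delta
                out = np.zeros(J)
                out[(new <= GAMMA0_LO) | (new >= GAMMA0_HI)] = -np.inf
                return out

            def ap_g0(accept, delta, k=k):
                state.gamma0[accept, k] += delta[accept]

            acc = shift_update(k, sp_s, sp_f_idx, J, ones_T, step_shift_g0[:, k], dp_g0, ap_g0)
            if adapting:
                step_shift_g0[:, k] *= np.exp(adapt * (acc - target))

            # lake intercept + its thetas
            def dp_om(delta, k=k):
                om = state.omega[:, k]
                return -((om + delta) ** 2 - om**2) / (2.0 * state.sig_omega[k] ** 2)

            def ap_om(accept, delta, k=k):
                state.omega[accept, k] += delta[accept]

            acc = shift_update(k, lake_s, lake_f, L, ones_T, step_shift_om[:, k], dp_om, ap_om)
            if adapting:
                step_shift_om[:, k] *= np.exp(adapt * (acc - target))

            ps = _PARAM_IDX_TO_SLOPE.get(k)
            if ps is None:
                continue
            # species slope + its thetas (shift scaled by the covariate)
            def dp_tau(delta, ps=ps):
                tv = state.tau[:, ps]
                return -((tv + delta) ** 2 - tv**2) / (2.0 * state.sig_tau[ps] ** 2)

            def ap_tau(accept, delta, ps=ps):
                state.tau[accept, ps] += delta[accept]

            acc = shift_update(k, sp_s, sp_f_idx, J, T, step_shift_tau[:, ps], dp_tau, ap_tau)
            if adapting:
                step_shift_tau[:, ps] *= np.exp(adapt * (acc - target))

            # global slope + every theta
            def dp_g1(delta, ps=ps):
                g = state.gamma1[ps]
                return -0.5 * ((g + delta) ** 2 - g**2)

            def ap_g1(accept, delta, ps=ps):
                state.gamma1[ps] += delta[0]

            acc = shift_update(
                k, zeros_S, zeros_F, 1, T, np.array([step_shift_g1[ps]]), dp_g1, ap_g1
            )
            if adapting:
                step_shift_g1[ps] *= np.exp(adapt * (float(acc[0]) - target))

        # --- lake-level joint shift: omega[l, :] and every theta of lake l
        # move together with a covariance-adapted 4-d jump (acceptance picks
        # up the omega prior since omega is not flat)
        zl = rng.standard_normal((L, 4))
        jumpl = lam_oml[:, None] * np.einsum("lik,lk->li", om_chol, zl)
        theta_prop = state.theta + jumpl[lake_s]
        bad_s = np.any((theta_prop < lo4) | (theta_prop > hi4), axis=1)
        ok_l = ~(np.bincount(lake_s, weights=bad_s.astype(float), minlength=L) > 0)
        theta_prop = np.where(ok_l[lake_s, None], theta_prop, state.theta)
        if N:
            logmu_p, quad_p, dlll = _delta_loglik(
                theta_prop, age, logy, sof, lake_f, inv2s2_f, quad, L
            )
        else:
            dlll = np.zeros(L)
        om_new = state.omega + jumpl
        dprl = (
            -((om_new**2 - state.omega**2) / (2.0 * state.sig_omega**2))
        ).sum(axis=1)
        acceptl = np.log(rng.uniform(size=L)) < np.where(ok_l, dlll + dprl, -np.inf)
        if np.any(acceptl):
            acc_s = acceptl[lake_s]
            state.theta[acc_s] = theta_prop[acc_s]
            state.omega[acceptl] += jumpl[acceptl]
            if N:
                f_acc = acceptl[lake_f]
                logmu[f_acc] = logmu_p[f_acc]
                quad[f_acc] = quad_p[f_acc]
        if adapting:
            lam_oml *= np.exp(adapt * (acceptl.astype(float) - 0.25))
            om_count += 1
            d0 = state.omega - om_mean
            om_mean += d0 / om_count
            om_m2 += d0[:, :, None] * (state.omega - om_mean)[:, None, :]
            if om_count > 100 and it % 25 == 0:
                cov = om_m2 / (om_count - 1)
                cov[:, np.arange(4), np.arange(4)] += 1e-8
                om_chol = np.linalg.cholesky(cov) * (2.38 / 2.0)

        # --- recentering sweeps along the redundant directions
        # gamma0 (flat prior) vs the lake-effect mean: shift delta keeps phi
        # unchanged, so its conditional comes from the omega prior alone.
        for k in range(4):
            sd = state.sig_omega[k] / np.sqrt(L)
            mean = float(state.omega[:, k].mean())
            lo = GAMMA0_LO - float(state.gamma0[:, k].min())
            hi = GAMMA0_HI - float(state.gamma0[:, k].max())
            if lo < hi:
                delta = float(truncnorm_draw(rng, np.array(mean), sd, lo, hi))
                state.gamma0[:, k] += delta
                state.omega[:, k] -= delta
        # gamma1 (N(0,1) prior) vs the species-slope mean
        for ps in range(3):
            prec = 1.0 + J / state.sig_tau[ps] ** 2
            mean = (
                -state.gamma1[ps] + float(state.tau[:, ps].sum()) / state.sig_tau[ps] ** 2
            ) / prec
            delta = mean + rng.standard_normal() / np.sqrt(prec)
            state.gamma1[ps] += delta
            state.tau[:, ps] -= delta

        # --- scale parameters, log-scale random-walk MH
        phi = linear_predictor(state, data)
        resid2 = (state.theta - phi) ** 2

        def mh_sigma(cur, step, ss, n):
            prop = cur * math.exp(step * rng.standard_normal())
            def tgt(s):
                # -n log s - ss/(2 s^2) + scale prior + log-scale Jacobian
                return (1.0 - n) * math.log(s) - ss / (2.0 * s * s) + _prior_sd(s)
            log_acc = tgt(prop) - tgt(cur)
            return (prop, True) if math.log(rng.uniform()) < log_acc else (cur, False)

        for k in range(4):
            cur = state.sig_phi[k]
            new, acc = mh_sigma(cur, step_sig_phi[k], float(resid2[:, k].sum()), S)
            state.sig_phi[k] = new
            if adapting:
                step_sig_phi[k] *= np.exp(adapt * (float(acc) - target))
        for i in range(3):
            ss = float(np.sum(state.tau[:, i] ** 2))
            new, acc = mh_sigma(state.sig_tau[i], step_sig_tau[i], ss, J)
            state.sig_tau[i] = new
            if adapting:
                step_sig_tau[i] *= np.exp(adapt * (float(acc) - target))
        for k in range(4):
            ss = float(np.sum(state.omega[:, k] ** 2))
            new, acc = mh_sigma(state.sig_omega[k], step_sig_omega[k], ss, L)
            state.sig_omega[k] = new
            if adapting:
                step_sig_omega[k] *= np.exp(adapt * (float(acc) - target))
        # --- non-centred scale moves: rescale children with their SD so the
        # sampler can cross the funnel (density x Jacobian cancel exactly;
        # acceptance is likelihood/middle-layer change + SD prior + proposal
        # Jacobian)
        phi = linear_predictor(state, data)
        for k in range(4):
            cur = state.sig_phi[k]
            prop = cur * np.exp(step_ncp_phi[k] * rng.standard_normal())
            ratio = prop / cur
            col = phi[:, k] + ratio * (state.theta[:, k] - phi[:, k])
            if np.all((col >= lo4[k]) & (col <= hi4[k])):
                theta_prop = state.theta.copy()
                theta_prop[:, k] = col
                if N:
                    logmu_p, quad_p, dll_arr = _delta_loglik(
                        theta_prop, age, logy, sof, zeros_F, inv2s2_f, quad, 1
                    )
                    dll = float(dll_arr[0])
                else:
                    dll = 0.0
                dpr = _prior_sd(prop) - _prior_sd(cur) + math.log(prop / cur)
                acc = math.log(rng.uniform()) < dll + dpr
                if acc:
                    state.sig_phi[k] = prop
                    state.theta[:, k] = col
                    if N:
                        logmu, quad = logmu_p, quad_p
                if adapting:
                    step_ncp_phi[k] *= np.exp(adapt * (float(acc) - target))
        for k in range(4):
            cur = state.sig_omega[k]
            prop = cur * np.exp(step_ncp_om[k] * rng.standard_normal())
            om_new = (prop / cur) * state.omega[:, k]
            dphi = om_new[lake_s] - state.omega[lake_s, k]
            r = state.theta[:, k] - phi[:, k]
            dmid = -float(
                np.sum((r - dphi) ** 2 - r**2) / (2.0 * state.sig_phi[k] ** 2)
            )
            dpr = _prior_sd(prop) - _prior_sd(cur) + math.log(prop / cur)
            acc = math.log(rng.uniform()) < dmid + dpr
            if acc:
                state.sig_omega[k] = prop
                state.omega[:, k] = om_new
                phi[:, k] += dphi
            if adapting:
                step_ncp_om[k] *= np.exp(adapt * (float(acc) - target))
        for ps, k in ((0, 1), (1, 2), (2, 3)):
            cur = state.sig_tau[ps]
            prop = cur * np.exp(step_ncp_tau[ps] * rng.standard_normal())
            tau_new = (prop / cur) * state.tau[:, ps]
            dphi = (tau_new[sp_s] - state.tau[sp_s, ps]) * T
            r = state.theta[:, k] - phi[:, k]
            dmid = -float(
                np.sum((r - dphi) ** 2 - r**2) / (2.0 * state.sig_phi[k] ** 2)
            )
            dpr = _prior_sd(prop) - _prior_sd(cur) + math.log(prop / cur)
            acc = math.log(rng.uniform()) < dmid + dpr
            if acc:
                state.sig_tau[ps] = prop
                state.tau[:, ps] = tau_new
                phi[:, k] += dphi
            if adapting:
                step_ncp_tau[ps] *= np.exp(adapt * (float(acc) - target))

        if N:
            ss_j = np.bincount(sp_f, weights=quad, minlength=J)
        else:
            ss_j = np.zeros(J)
        for j in range(J):
            new, acc = mh_sigma(
                state.sigma_obs[j], step_sigma_obs[j], float(ss_j[j]), float(n_fish_per_species[j])
            )
            state.sigma_obs[j] = new
            if adapting:
                step_sigma_obs[j] *= np.exp(adapt * (float(acc) - target))
        if N:
            inv2s2_f = 1.0 / (2.0 * state.sigma_obs[sp_f] ** 2)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if keep_i < n_keep:
                out[keep_i] = _snapshot(state, data)
                keep_i += 1

    info = {"theta_accept": (acc_counts / max(acc_total, 1)).tolist()}
    return out[:keep_i], info


_PARAM_IDX_TO_SLOPE = {1: 0, 2: 1, 3: 2}


def fit_growth_model(
    data: GrowthData | pd.DataFrame,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
    thermal: pd.DataFrame | None = None,
    gamma_prior_on: str = "sd",
) -> PosteriorDraws:
    """Sample the hierarchical growth posterior.

    ``data`` is a :class:`GrowthData` (or an aged fish table together with
    ``thermal``).  Chains are seeded independently from ``seed``; the same
    seed reproduces the draws exactly.  Raises if the posterior is not
    finite at initialisation.
    """
    if not isinstance(data, GrowthData):
        if thermal is None:
            raise ValueError("pass a GrowthData or a fish table plus thermal table")
        data = GrowthData.from_frames(data, thermal)
    config = mcmc_config or MCMCConfig()
    names = _monitored_names(data)
    chains = []
    infos = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(seed), 7, c])
        check_state = _initial_state(data, np.random.default_rng([int(seed), 7, c]))
        lp0 = log_posterior(check_state, data, gamma_prior_on)
        if not np.isfinite(lp0):
            raise RuntimeError(
                "non-finite log posterior at initialisation "
                f"(chain {c}): check data supports and scales"
            )
        draws, info = _run_growth_chain(data, config, rng, gamma_prior_on)
        chains.append(draws)
        infos.append(info)
    n = min(d.shape[0] for d in chains)
    arr = np.stack([d[:n] for d in chains])
    return PosteriorDraws(
        names,
        arr,
        meta={
            "seed": int(seed),
            "chains": config.chains,
            "iterations": config.iterations,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "model": "growth",
            "gamma_prior_on": gamma_prior_on,
            "species": data.species_names,
            "chain_info": infos,
        },
    )
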