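"""Longevity regression: 95th-percentile age versus temperature.

The 95th percentile of observed ages in a population (a95) is the proxy
for maximum age.  It is regressed on the scaled thermal covariate with a
Gaussian likelihood, species intercept offsets, a species-by-temperature
interaction and a lake random intercept.  Coefficients get vague
Normal(0, 10) priors; the lake and residual SDs get half-Normal(0, 10)
priors (a literal Normal(0, 10) cannot apply to a positive scale).

The sampler is conjugate Gibbs for the coefficients and lake effects with
adaptive log-scale random-walk Metropolis for the two SDs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, PosteriorDraws, sd_log_prior

__all__ = [
    "compute_a95",
    "build_longevity_records",
    "fit_longevity_model",
    "amax_linear_predictor",
]

_LOG_2PI = np.log(2.0 * np.pi)


def compute_a95(ages, quantile_method: str = "linear") -> float:
    """95th-percentile age by linear interpolation of order statistics."""
    a = np.asarray(ages, dtype=float)
    if a.size == 0:
        raise ValueError("empty age sample")
    return float(np.quantile(a, 0.95, method=quantile_method))


def build_longevity_records(
    aged_records: pd.DataFrame,
    min_fish: int = 1,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Per-survey a95 table from a fully aged sample.

    By default this runs on the ALK-expanded sample (every measured fish,
    aged); pass the aged subsample instead to compute a95 on aged fish
    only.  Surveys with fewer than ``min_fish`` fish are skipped.
    """
    rows = []
    for (sp, lake, year), grp in aged_records.groupby(
        ["species", "lake_id", "year"], sort=True
    ):
        ages = grp["age_yr"].dropna()
        if len(ages) < min_fish:
            continue
        rows.append(
            {
                "species": sp,
                "lake_id": lake,
                "year": year,
                "a95": compute_a95(ages, quantile_method),
                "n_fish": len(ages),
            }
        )
    return pd.DataFrame(rows)


def _design(records: pd.DataFrame):
    species = sorted(records["species"].unique())
    lakes = sorted(records["lake_id"].unique())
    sp_idx = records["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    lake_idx = records["lake_id"].map({s: i for i, s in enumerate(lakes)}).to_numpy()
    T = records["t_scaled"].to_numpy(dtype=float)
    n = len(records)
    names = ["intercept"]
    cols = [np.ones(n)]
    for j, s in enumerate(species[1:], start=1):
        names.append(f"species[{s}]")
        cols.append((sp_idx == j).astype(float))
    names.append("slope_T")
    cols.append(T)
    for j, s in enumerate(species[1:], start=1):
        names.append(f"interaction[{s}]")
        cols.append(T * (sp_idx == j))
    return np.column_stack(cols), names, species, lakes, lake_idx


def fit_longevity_model(
    records: pd.DataFrame,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the Bayesian longevity regression posterior.

    ``records`` needs species, lake_id, a95 and t_scaled columns.  At
    least 2 lakes are required (the lake random effect is unidentifiable
    otherwise).  Same seed, same draws.
    """
    if records["lake_id"].nunique() < 2:
        raise ValueError("need >= 2 lakes to identify the lake random effect")
    config = mcmc_config or MCMCConfig(chains=3, iterations=5000, burn_in=2000, thin=2)
    X, coef_names, species, lakes, lake_idx = _design(records)
    y = records["a95"].to_numpy(dtype=float)
    n, P = X.shape
    L = len(lakes)
    n_per_lake = np.bincount(lake_idx, minlength=L).astype(float)
    XtX = X.T @ X
    prior_prec = np.eye(P) / 100.0  # Normal(0, 10) on every coefficient

    names = coef_names + ["sigma_lake", "sigma_resid"]
    all_chains = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(seed), 11, c])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = beta + rng.normal(0.0, 0.1, size=P)
        u = np.zeros(L)
        resid = y - X @ beta
        sigma_resid = float(np.clip(np.std(resid), 0.05, 10.0)) * np.exp(
            rng.normal(0.0, 0.1)
        )
        sigma_lake = 0.5 * np.exp(rng.normal(0.0, 0.2))
        step_sr, step_sl, step_ncl = 0.2, 0.4, 0.3
        adapt, target = 0.05, 0.44

        keep = np.empty((config.retained, len(names)))
        ki = 0
        for it in range(config.iterations):
            adapting = it < config.burn_in
            # coefficients | rest
            prec = XtX / sigma_resid**2 + prior_prec
            cov = np.linalg.inv(prec)
            mean = cov @ (X.T @ (y - u[lake_idx])) / sigma_resid**2
            beta = mean + np.linalg.cholesky(cov) @ rng.standard_normal(P)
            # lake effects | rest
            r = y - X @ beta
            prec_u = n_per_lake / sigma_resid**2 + 1.0 / sigma_lake**2
            mean_u = np.bincount(lake_idx, weights=r, minlength=L) / sigma_resid**2 / prec_u
            u = mean_u + rng.standard_normal(L) / np.sqrt(prec_u)
            # residual SD | rest (half-Normal(0,10) prior, log-scale RW)
            ss = float(np.sum((r - u[lake_idx]) ** 2))
            prop = sigma_resid * np.exp(step_sr * rng.standard_normal())
            def tgt_resid(s):
                return (
                    -n * np.log(s)
                    - ss / (2 * s * s)
                    + sd_log_prior(s, "half_normal_10")
                    + np.log(s)
                )
            acc = np.log(rng.uniform()) < tgt_resid(prop) - tgt_resid(sigma_resid)
            if acc:
                sigma_resid = prop
            if adapting:
                step_sr *= np.exp(adapt * (float(acc) - target))
            # lake SD | rest
            ssu = float(np.sum(u * u))
            prop = sigma_lake * np.exp(step_sl * rng.standard_normal())
            def tgt_lake(s):
                return (
                    -L * np.log(s)
                    - ssu / (2 * s * s)
                    + sd_log_prior(s, "half_normal_10")
                    + np.log(s)
                )
            acc = np.log(rng.uniform()) < tgt_lake(prop) - tgt_lake(sigma_lake)
            if acc:
                sigma_lake = prop
            if adapting:
                step_sl *= np.exp(adapt * (float(acc) - target))
            # non-centred companion move: rescale the lake effects with
            # their SD so the two can cross the funnel together (the
            # effect prior and the Jacobian cancel exactly)
            prop = sigma_lake * np.exp(step_ncl * rng.standard_normal())
            u_new = (prop / sigma_lake) * u
            ss_old = float(np.sum((r - u[lake_idx]) ** 2))
            ss_new = float(np.sum((r - u_new[lake_idx]) ** 2))
            dll = -(ss_new - ss_old) / (2 * sigma_resid**2)
            dpr = (
                sd_log_prior(prop, "half_normal_10")
                - sd_log_prior(sigma_lake, "half_normal_10")
                + np.log(prop / sigma_lake)
            )
            acc = np.log(rng.uniform()) < dll + dpr
            if acc:
                sigma_lake = prop
                u = u_new
            if adapting:
                step_ncl *= np.exp(adapt * (float(acc) - target))

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                if ki < config.retained:
                    keep[ki] = np.concatenate([beta, [sigma_lake, sigma_resid]])
                    ki += 1
        all_chains.append(keep[:ki])

    nmin = min(k.shape[0] for k in all_chains)
    arr = np.stack([k[:nmin] for k in all_chains])
    return PosteriorDraws(
        names,
        arr,
        meta={
            "seed": int(seed),
            "chains": config.chains,
            "iterations": config.iterations,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "model": "longevity",
            "species": species,
        },
    )


def amax_linear_predictor(
    draws: PosteriorDraws, species: str, t_scaled: float
) -> np.ndarray:
    """Per-draw maximum-age prediction for one species at one temperature."""
    species_list = draws.meta["species"]
    mu = draws.flat("intercept") + draws.flat("slope_T") * t_scaled
    if species != species_list[0]:
        mu = (
            mu
            + draws.flat(f"species[{species}]")
            + draws.flat(f"interaction[{species}]") * t_scaled
        )
    return mu
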