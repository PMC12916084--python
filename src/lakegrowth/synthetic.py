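"""Synthetic age-length survey generator.

Emulates the statistical structure of standardised inland-lake fisheries
monitoring data: lakes spread along a thermal gradient, several species with
distinct baseline growth, repeated lake-year surveys, biphasic lognormal
length-at-age, temperature effects on juvenile growth / maturation age /
adult growth / longevity, and length-stratified age subsampling.  Every
downstream stage of the pipeline can therefore be tested against known
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biphasic import PARAM_NAMES, SLOPE_PARAMS, THETA_HI, THETA_LO, biphasic_mean
from .thermal import GDD_BASE

__all__ = [
    "TrueHyperparams",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_daily_temps",
    "simulate_populations",
    "simulate_fish",
    "mask_ages",
    "simulate_dataset",
]

_SEASON_PEAK_DOY = 200  # mid-July surface-temperature peak


def _default_gamma0(n_species: int) -> dict[str, np.ndarray]:
    """Species baselines spanning a slow-growing panfish to a fast apex fish."""
    lo = {"alpha": 0.5, "beta1": 3.0, "amat": 2.0, "beta2": 1.2}
    hi = {"alpha": 15.0, "beta1": 10.0, "amat": 4.5, "beta2": 4.0}
    w = np.linspace(0.0, 1.0, n_species) if n_species > 1 else np.array([0.5])
    return {p: lo[p] + (hi[p] - lo[p]) * w for p in PARAM_NAMES}


@dataclass
class TrueHyperparams:
    """Generating values of the growth hierarchy's hyperparameters.

    ``gamma0`` holds species baselines for each biphasic parameter;
    ``gamma1`` the global temperature slopes (on the z-scored covariate) for
    beta1, amat and beta2; the sigma terms are the SDs of species random
    slopes, lake random intercepts, the parameter-level noise and the
    per-species lognormal observation scale.
    """

    gamma0: dict[str, np.ndarray]
    gamma1: dict[str, float] = field(
        default_factory=lambda: {"beta1": 0.5, "amat": -0.5, "beta2": 0.0}
    )
    sigma_tau: dict[str, float] = field(
        default_factory=lambda: {p: 0.1 for p in SLOPE_PARAMS}
    )
    sigma_omega: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.3, "beta1": 0.25, "amat": 0.2, "beta2": 0.15}
    )
    sigma_phi: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.15, "beta1": 0.3, "amat": 0.25, "beta2": 0.15}
    )
    obs_sigma: np.ndarray | None = None  # per-species lognormal scale

    @classmethod
    def default(cls, n_species: int) -> "TrueHyperparams":
        return cls(
            gamma0=_default_gamma0(n_species),
            obs_sigma=np.full(n_species, 0.12),
        )


@dataclass
class SimulationConfig:
    """Study-design knobs of the synthetic survey generator."""

    n_lakes: int = 40
    n_species: int = 2
    years_per_lake: int = 2
    fish_per_survey: int = 60
    # int >= 1: per-length-bin aged quota; float in (0, 1]: aged fraction per bin
    aged_fraction_or_quota: float | int = 10
    bin_width: float = 1.0
    true_hyperparams: TrueHyperparams | None = None
    # per-species (intercept, slope on scaled T) for the true a95-style max age
    longevity_intercepts: np.ndarray | None = None
    longevity_slopes: np.ndarray | None = None
    longevity_lake_sd: float = 1.0
    # annual thermal energy (degC*day) spanned by the lake gradient
    climate_gradient: tuple[float, float] = (1200.0, 3200.0)
    seasonal_amplitude: float = 14.0
    day_noise_sd: float = 1.0
    first_survey_year: int = 2012
    window: int = 10
    survival_rate: float = 0.65  # geometric age-structure parameter
    min_age: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lakes", "n_species", "years_per_lake", "fish_per_survey"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        q = self.aged_fraction_or_quota
        if isinstance(q, (int, np.integer)) and not isinstance(q, bool):
            if q < 1:
                raise ValueError("aged quota must be >= 1")
        else:
            if not (0.0 < q <= 1.0):
                raise ValueError("aged fraction must lie in (0, 1]")
        if not (0.0 < self.survival_rate < 1.0):
            raise ValueError("survival_rate must lie in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.true_hyperparams is None:
            self.true_hyperparams = TrueHyperparams.default(self.n_species)
        if self.true_hyperparams.obs_sigma is None:
            self.true_hyperparams.obs_sigma = np.full(self.n_species, 0.12)
        if np.any(np.asarray(self.true_hyperparams.obs_sigma) <= 0):
            raise ValueError("obs_sigma must be > 0")
        if self.longevity_intercepts is None:
            self.longevity_intercepts = np.linspace(9.0, 16.0, self.n_species)
        if self.longevity_slopes is None:
            self.longevity_slopes = np.full(self.n_species, -0.4)

    @property
    def species_names(self) -> list[str]:
        return [f"species_{chr(ord('A') + j)}" for j in range(self.n_species)]

    @property
    def survey_years(self) -> np.ndarray:
        return np.arange(
            self.first_survey_year, self.first_survey_year + self.years_per_lake
        )


@dataclass
class SimulationTruth:
    """Latent generating state, joinable to fish records by survey key."""

    surveys: pd.DataFrame  # species, lake_id, year, t_scaled, alpha..beta2, max_age
    omega: pd.DataFrame  # lake_id x parameter true lake effects
    tau: pd.DataFrame  # species x parameter true species slopes
    config: SimulationConfig


def _seasonal_cycle(mean_temp: float, amplitude: float, doy: np.ndarray) -> np.ndarray:
    return mean_temp + amplitude * np.cos(
        2.0 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.0
    )


def _noise_free_annual_gdd(mean_temp: float, amplitude: float) -> float:
    doy = np.arange(1, 366)
    t = _seasonal_cycle(mean_temp, amplitude, doy)
    return float(np.clip(t - GDD_BASE, 0.0, None).sum())


def _mean_temp_for_gdd(target: float, amplitude: float) -> float:
    """Invert the noise-free seasonal cycle for a target annual GDD (bisection)."""
    lo, hi = -30.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _noise_free_annual_gdd(mid, amplitude) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def lake_mean_temps(config: SimulationConfig) -> np.ndarray:
    """Per-lake annual mean temperatures realising the climate gradient."""
    lo, hi = config.climate_gradient
    if config.n_lakes == 1:
        targets = np.array([0.5 * (lo + hi)])
    else:
        targets = np.linspace(lo, hi, config.n_lakes)
    return np.array(
        [_mean_temp_for_gdd(t, config.seasonal_amplitude) for t in targets]
    )


def simulate_daily_temps(config: SimulationConfig) -> pd.DataFrame:
    """Daily surface temperatures for every lake over the simulated span.

    A sinusoidal annual cycle plus a lake-specific offset spanning the
    climate gradient plus Gaussian day noise; complete calendar coverage
    from ``window`` years before the first survey through the last survey
    year.
    """
    first_year = config.first_survey_year - config.window + 1
    last_year = int(config.survey_years[-1])
    if last_year < first_year:
        raise ValueError("nonpositive simulated span")
    rng = np.random.default_rng([config.seed, 101])
    means = lake_mean_temps(config)
    dates = pd.date_range(f"{first_year}-01-01", f"{last_year}-12-31", freq="D")
    doy = dates.day_of_year.to_numpy().astype(float)
    frames = []
    for l in range(config.n_lakes):
        base = _seasonal_cycle(means[l], config.seasonal_amplitude, doy)
        noise = (
            rng.normal(0.0, config.day_noise_sd, size=len(dates))
            if config.day_noise_sd > 0
            else 0.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "lake_id": f"lake_{l:03d}",
                    "date": dates.strftime("%Y-%m-%d"),
                    "temp_c": base + noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _truncnorm_draw(rng, mean, sd, lo, hi):
    """Vectorised truncated-normal draw; degenerates to clip when sd == 0."""
    mean = np.asarray(mean, dtype=float)
    if sd <= 0:
        return np.clip(mean, lo, hi)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.uniform(size=mean.shape)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_populations(
    config: SimulationConfig, t_scaled_by_lake_year: pd.DataFrame
) -> SimulationTruth:
    """Draw true growth and longevity parameters for every survey.

    For p in {beta1, amat, beta2} the linear predictor is
    ``gamma0_p(species) + (gamma1_p + tau_jp) * T + omega_lp``; for alpha it
    is ``gamma0_alpha(species) + omega_l_alpha``.  Survey-level parameters
    are Normal(phi, sigma_phi_p) truncated to their supports.  The true
    maximum age is the longevity linear predictor plus a lake effect,
    floored at ``amat + 1``.
    """
    hp = config.true_hyperparams
    rng = np.random.default_rng([config.seed, 202])
    lakes = sorted(t_scaled_by_lake_year["lake_id"].unique())
    lake_idx = {lk: i for i, lk in enumerate(lakes)}

    omega = {
        p: rng.normal(0.0, hp.sigma_omega[p], size=len(lakes)) for p in PARAM_NAMES
    }
    tau = {p: rng.normal(0.0, hp.sigma_tau[p], size=config.n_species) for p in SLOPE_PARAMS}
    omega_longevity = rng.normal(0.0, config.longevity_lake_sd, size=len(lakes))

    ly = t_scaled_by_lake_year.sort_values(["lake_id", "year"]).reset_index(drop=True)
    rows = []
    bounds = {p: (THETA_LO[i], THETA_HI[i]) for i, p in enumerate(PARAM_NAMES)}
    for j, sp in enumerate(config.species_names):
        for _, r in ly.iterrows():
            l = lake_idx[r["lake_id"]]
            T = float(r["t_scaled"])
            theta = {}
            for p in PARAM_NAMES:
                phi = hp.gamma0[p][j] + omega[p][l]
                if p in SLOPE_PARAMS:
                    phi += (hp.gamma1[p] + tau[p][j]) * T
                lo, hi = bounds[p]
                theta[p] = float(
                    _truncnorm_draw(rng, np.array(phi), hp.sigma_phi[p], lo, hi)
                )
            max_age = (
                config.longevity_intercepts[j]
                + config.longevity_slopes[j] * T
                + omega_longevity[l]
            )
            max_age = max(float(max_age), theta["amat"] + 1.0)
            rows.append(
                {
                    "species": sp,
                    "lake_id": r["lake_id"],
                    "year": int(r["year"]),
                    "t_scaled": T,
                    **theta,
                    "max_age": max_age,
                }
            )
    surveys = pd.DataFrame(rows)
    omega_df = pd.DataFrame({"lake_id": lakes, **{p: omega[p] for p in PARAM_NAMES}})
    tau_df = pd.DataFrame(
        {"species": config.species_names, **{p: tau[p] for p in SLOPE_PARAMS}}
    )
    return SimulationTruth(surveys=surveys, omega=omega_df, tau=tau_df, config=config)


# Aging-structure labels assigned to sampled fish (no error model attached).
_STRUCTURES = ("otolith", "scale", "spine", "cleithrum", "fin_ray")
_STRUCTURE_P = (0.45, 0.35, 0.1, 0.05, 0.05)


def simulate_fish(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Fully aged fish records for every survey in ``truth``.

    Ages follow a geometric-like decreasing distribution truncated at the
    population's true maximum age, so young fish dominate; length is a
    lognormal draw whose median equals the biphasic mean at the fish's age.
    """
    if np.any(np.asarray(config.true_hyperparams.obs_sigma) <= 0):
        raise ValueError("obs_sigma must be > 0")
    rng = np.random.default_rng([config.seed, 303])
    sp_index = {sp: j for j, sp in enumerate(config.species_names)}
    frames = []
    fid = 0
    for _, s in truth.surveys.iterrows():
        j = sp_index[s["species"]]
        amax = int(np.floor(s["max_age"]))
        ages_support = np.arange(config.min_age, max(amax, config.min_age) + 1)
        pmf = config.survival_rate ** (ages_support - config.min_age)
        pmf /= pmf.sum()
        n = config.fish_per_survey
        ages = rng.choice(ages_support, size=n, p=pmf)
        mu = biphasic_mean(s["alpha"], s["beta1"], s["beta2"], s["amat"], ages)
        sigma = float(config.true_hyperparams.obs_sigma[j])
        lengths = np.exp(np.log(np.maximum(mu, 1e-12)) + rng.normal(0.0, sigma, n))
        structures = rng.choice(_STRUCTURES, size=n, p=_STRUCTURE_P)
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": np.arange(fid, fid + n),
                    "species": s["species"],
                    "lake_id": s["lake_id"],
                    "year": int(s["year"]),
                    "length_cm": lengths,
                    "age_yr": ages.astype(float),
                    "structure": structures,
                    "aged_flag": True,
                }
            )
        )
        fid += n
    return pd.concat(frames, ignore_index=True)


def mask_ages(records: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Retain age only for a length-stratified subsample of each survey.

    Within each ``bin_width`` length bin of each survey, up to the
    configured quota (or fraction) of fish keep their age; the rest have
    ``age_yr`` set missing and ``aged_flag`` cleared.  The total record
    count is unchanged.
    """
    q = config.aged_fraction_or_quota
    is_count = isinstance(q, (int, np.integer)) and not isinstance(q, bool)
    if is_count and q < 1:
        raise ValueError("aged quota must be >= 1")
    rng = np.random.default_rng([config.seed, 404])
    out = records.copy()
    bins = np.floor(out["length_cm"].to_numpy() / config.bin_width).astype(int)
    out["_bin"] = bins
    keep = np.zeros(len(out), dtype=bool)
    for _, grp in out.groupby(["species", "lake_id", "year", "_bin"], sort=True):
        idx = grp.index.to_numpy()
        n_keep = int(q) if is_count else int(np.ceil(q * len(idx)))
        n_keep = min(n_keep, len(idx))
        chosen = rng.choice(idx, size=n_keep, replace=False)
        keep[out.index.get_indexer(chosen)] = True
    out.loc[~keep, "age_yr"] = np.nan
    out["aged_flag"] = keep
    return out.drop(columns="_bin")


def simulate_a95_records(
    n_lakes: int = 40,
    n_species: int = 3,
    intercepts: np.ndarray | None = None,
    slopes: np.ndarray | None = None,
    lake_sd: float = 1.0,
    resid_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-population 95th-percentile-age records.

    Draws one record per lake x species from the Gaussian longevity
    regression itself: ``a95 = intercept_j + slope_j * T_l + u_l + eps``
    with lake effects ``u_l ~ N(0, lake_sd)`` and residuals
    ``N(0, resid_sd)``; the lake covariate ``T`` is z-scored.  Used for
    parameter-recovery and calibration checks of the longevity model.
    """
    rng = np.random.default_rng([int(seed), 505])
    if intercepts is None:
        intercepts = np.linspace(8.0, 16.0, n_species)
    if slopes is None:
        slopes = np.full(n_species, -0.4)
    T = np.linspace(-1.0, 1.0, n_lakes)
    if n_lakes > 1:
        T = (T - T.mean()) / T.std()
    u = rng.normal(0.0, lake_sd, n_lakes)
    rows = []
    for j in range(n_species):
        eps = rng.normal(0.0, resid_sd, n_lakes)
        a95 = intercepts[j] + slopes[j] * T + u + eps
        for l in range(n_lakes):
            rows.append(
                {
                    "species": f"species_{chr(ord('A') + j)}",
                    "lake_id": f"lake_{l:03d}",
                    "year": 2012,
                    "a95": float(a95[l]),
                    "n_fish": 60,
                    "t_scaled": float(T[l]),
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig):
    """Run the full generative chain; returns (daily_temps, thermal_table,
    scaler, truth, fish, masked_fish).

    The thermal covariate fed to the population generator is the
    z-scored trailing-window GDD mean computed by the thermal module from
    the generated daily series, exactly as the analysis pipeline would.
    """
    from .thermal import thermal_covariates

    daily = simulate_daily_temps(config)
    lakes = sorted(daily["lake_id"].unique())
    surveys = pd.DataFrame(
        [(lk, int(y)) for lk in lakes for y in config.survey_years],
        columns=["lake_id", "year"],
    )
    thermal_table, scaler = thermal_covariates(daily, surveys, window=config.window)
    truth = simulate_populations(config, thermal_table[["lake_id", "year", "t_scaled"]])
    fish = simulate_fish(truth, config)
    masked = mask_ages(fish, config)
    return daily, thermal_table, scaler, truth, fish, masked
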