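"""Shared MCMC plumbing: sampler configuration and posterior-draw storage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MCMCConfig", "PosteriorDraws", "STUDY_SCALE_GROWTH_MCMC", "STUDY_SCALE_LONGEVITY_MCMC"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout: total iterations include burn-in; draws retained after
    burn-in at the thinning stride."""

    chains: int = 3
    iterations: int = 5000
    burn_in: int = 2000
    thin: int = 2

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must lie in [0, iterations)")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


# The original study's full-scale settings, available behind a flag.
STUDY_SCALE_GROWTH_MCMC = MCMCConfig(chains=3, iterations=125_000, burn_in=30_000, thin=10)
STUDY_SCALE_LONGEVITY_MCMC = MCMCConfig(chains=3, iterations=50_000, burn_in=40_000, thin=100)


@dataclass
class PosteriorDraws:
    """Retained draws: (chains, iterations, parameters) with names and
    sampler metadata (seed, config, acceptance rates...)."""

    names: list[str]
    array: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("array must be (chains, draws, len(names))")
        if not np.all(np.isfinite(self.array)):
            raise ValueError("non-finite values in retained draws")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        return self.array[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter."""
        return self.get(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value) for CSV round trips."""
        c, d, p = self.array.shape
        chains = np.repeat(np.arange(c), d * p)
        draws = np.tile(np.repeat(np.arange(d), p), c)
        params = np.tile(np.array(self.names, dtype=object), c * d)
        return pd.DataFrame(
            {
                "chain": chains,
                "draw": draws,
                "parameter": params,
                "value": self.array.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "PosteriorDraws":
        names = list(dict.fromkeys(df["parameter"]))
        c = int(df["chain"].max()) + 1
        d = int(df["draw"].max()) + 1
        arr = np.empty((c, d, len(names)))
        pivot = df.pivot_table(
            index=["chain", "draw"], columns="parameter", values="value", sort=False
        )[names]
        arr = pivot.to_numpy().reshape(c, d, len(names))
        return cls(names, arr, meta or {})


def truncnorm_draw(rng: np.random.Generator, mean, sd, lo, hi):
    """Inverse-CDF truncated-normal draw (vectorised, generator-seeded)."""
    from scipy.special import ndtr, ndtri

    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(size=mean.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = ndtri(a + u * (b - a))
    out = mean + sd * np.where(np.isfinite(z), z, 0.0)
    return np.clip(out, lo, hi)


def sd_log_prior(sigma: np.ndarray | float, kind: str = "gamma_sd") -> float:
    """Log prior of a positive scale parameter.

    ``gamma_sd``: Gamma(1,1) (= Exp(1)) placed on the SD itself.
    ``gamma_var``: Gamma(1,1) on the variance, expressed as a density over
    the SD (includes the 2*sigma Jacobian).
    ``half_normal_10``: half-Normal(0, 10) on the SD.
    """
    s = np.asarray(sigma, dtype=float)
    if np.any(s <= 0):
        return -np.inf
    if kind == "gamma_sd":
        return float(np.sum(-s))
    if kind == "gamma_var":
        return float(np.sum(-s * s + np.log(2.0 * s)))
    if kind == "half_normal_10":
        return float(np.sum(-0.5 * (s / 10.0) ** 2))
    raise ValueError(f"unknown scale prior {kind!r}")
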