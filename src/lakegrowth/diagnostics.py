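"""MCMC convergence diagnostics and posterior-interval utilities.

Rank-normalised split-R-hat measures agreement between (split) chains; the
autocorrelation-based effective sample size measures information content
within chains; the highest-posterior-density (HPD) interval is the
narrowest interval holding a stated probability mass, and an effect is
called significant when its 95% HPD excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "split_rhat",
    "effective_sample_size",
    "hpd_interval",
    "hpd_significance",
    "ConvergenceReport",
    "convergence_report",
]

RHAT_THRESHOLD = 1.1
ESS_THRESHOLD = 300.0


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half (dropping a trailing odd draw)."""
    m, n = x.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Map pooled draws to normal scores via average fractional ranks."""
    shape = x.shape
    r = stats.rankdata(x.ravel(), method="average")
    z = stats.norm.ppf((r - 3.0 / 8.0) / (x.size + 0.25))
    return z.reshape(shape)


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalised split-R-hat for one parameter.

    ``draws`` is (chains, iterations) with >= 2 chains.  Values near 1
    indicate the chains agree; >= 1 up to numerical tolerance.
    """
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("split_rhat needs at least 2 chains")
    z = _rank_normalize(_split_chains(x))
    m, n = z.shape
    chain_means = z.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = z.var(axis=1, ddof=1).mean()
    if w <= 0:
        return np.inf if b > 0 else 1.0
    var_plus = (n - 1) / n * w + b / n
    # the raw estimator can dip below 1 by sampling noise; clamp to its floor
    return float(max(np.sqrt(var_plus / w), 1.0))


def _chain_autocov(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariances of each row via FFT."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS pooled across split chains.

    Uses the multi-chain combined autocorrelation with Geyer's initial
    positive / monotone sequence truncation.  Capped at the total draw
    count; a constant (zero-variance) input reports 0.
    """
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("effective_sample_size needs at least 2 chains")
    x = _split_chains(x)
    m, n = x.shape
    total = x.size
    chain_var = x.var(axis=1, ddof=1)
    w = chain_var.mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    if var_plus <= 0 or w <= 0:
        return 0.0

    acov = _chain_autocov(x)
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0

    # Geyer pairs: sum rho[2k] + rho[2k+1] while positive, then enforce
    # monotone nonincreasing partial sums.
    max_pairs = (n - 1) // 2
    tau = 1.0  # will accumulate -rho0 + 2*sum; start from pair sums directly
    pair_sums = []
    for k in range(max_pairs):
        s = rho[2 * k] + rho[2 * k + 1]
        if s <= 0:
            break
        pair_sums.append(s)
    if pair_sums:
        ps = np.minimum.accumulate(pair_sums)
        tau = -1.0 + 2.0 * float(np.sum(ps))
    tau = max(tau, 1.0 / np.log10(max(total, 10)))
    ess = total / tau
    return float(min(ess, total))


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` posterior mass (sorted window)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 4:
        raise ValueError("too few draws for an HPD interval")
    k = max(int(np.ceil(prob * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def hpd_significance(draws: np.ndarray, prob: float = 0.95):
    """HPD interval plus a flag: significant iff 0 lies outside it."""
    if np.asarray(draws).size < 100:
        raise ValueError("need at least 100 draws to assess significance")
    lo, hi = hpd_interval(draws, prob)
    return (lo, hi), not (lo <= 0.0 <= hi)


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat and ESS with pass flags at the reported bounds."""

    names: list[str]
    rhat: np.ndarray
    ess: np.ndarray
    rhat_threshold: float = RHAT_THRESHOLD
    ess_threshold: float = ESS_THRESHOLD

    @property
    def passed(self) -> bool:
        return bool(
            np.all(self.rhat < self.rhat_threshold)
            and np.all(self.ess > self.ess_threshold)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.names,
                "rhat": self.rhat,
                "ess": self.ess,
                "rhat_ok": self.rhat < self.rhat_threshold,
                "ess_ok": self.ess > self.ess_threshold,
            }
        )


def convergence_report(names, array) -> ConvergenceReport:
    """Diagnostics for a (chains, draws, parameters) array."""
    arr = np.asarray(array, dtype=float)
    rhats = np.array([split_rhat(arr[:, :, i]) for i in range(arr.shape[2])])
    esss = np.array([effective_sample_size(arr[:, :, i]) for i in range(arr.shape[2])])
    return ConvergenceReport(list(names), rhats, esss)
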