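"""Biphasic (hockey-stick) length-at-age model.

Length grows linearly at a juvenile rate ``beta1`` up to the change point
``amat`` (a proxy for age at maturity) and at an adult rate ``beta2``
thereafter; the two segments join continuously at the change point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiphasicParams", "biphasic_mean"]

# Supports of the survey-level growth parameters (alpha, beta1, amat, beta2).
PARAM_NAMES = ("alpha", "beta1", "amat", "beta2")
SLOPE_PARAMS = ("beta1", "amat", "beta2")
THETA_LO = np.array([0.0, 1e-9, 0.25, -np.inf])
THETA_HI = np.array([np.inf, np.inf, 30.0, np.inf])

# Predicted lengths are floored here before logs are taken.
MEAN_FLOOR = 1e-6


@dataclass(frozen=True)
class BiphasicParams:
    """Parameters of one population's growth curve.

    alpha : length at age 0 (cm)
    beta1 : juvenile growth rate (cm/yr), > 0
    beta2 : adult growth rate (cm/yr)
    amat  : change-point age (yr), > 0
    """

    alpha: float
    beta1: float
    beta2: float
    amat: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta1 <= 0:
            raise ValueError(f"beta1 must be > 0, got {self.beta1}")
        if self.amat <= 0:
            raise ValueError(f"amat must be > 0, got {self.amat}")

    def mean(self, age):
        return biphasic_mean(self.alpha, self.beta1, self.beta2, self.amat, age)


def biphasic_mean(alpha, beta1, beta2, amat, age):
    """Expected length (cm) at ``age`` under the biphasic model.

    ``alpha + beta1*a`` for ``a < amat`` and
    ``alpha + beta1*amat + beta2*(a - amat)`` for ``a >= amat``;
    continuous at the change point by construction.  All arguments
    broadcast; negative ages are rejected.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    juvenile = np.minimum(age, amat)
    adult = np.maximum(age - amat, 0.0)
    out = alpha + beta1 * juvenile + beta2 * adult
    if out.ndim == 0:
        return float(out)
    return out
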