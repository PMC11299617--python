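"""Poisson observation model for count-type scattering data.

Measured intensities are photon counts, so each observation is modelled as

    y_i ~ Poisson(lambda_i),      lambda_i = T * I_K(q_i, params),

where ``T`` is a pseudo-measurement time (count-scale multiplier; smaller
``T`` means noisier data).  The per-curve mean cost

    E(params) = (1/N) * sum_i [ lambda_i - y_i * ln lambda_i ]

relates to the likelihood through

    p(D | params, K) = C(D) * exp(-N * E),      C(D) = prod_i 1 / y_i!,

where ``C(D)`` depends on the data only.  ``C(D)`` is therefore dropped
from all costs and evidence values reported by this package: it is shared
by every candidate model for the same curve and cancels exactly in
posterior model probabilities.  Pass ``include_data_constant=True`` where
offered to add ``-sum_i ln y_i!`` back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .models import SphereMixtureParams, QGrid, intensity
from .priors import PriorSet, log_prior

__all__ = ["ScatteringCurve", "poisson_cost", "log_posterior_unnorm"]


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve with count semantics.

    Attributes
    ----------
    q : ndarray, shape (N,)
        Strictly increasing scattering-vector magnitudes, nm^-1.
    y : ndarray, shape (N,)
        Observed intensities (non-negative counts).
    T : float
        Pseudo-measurement time: Poisson means are ``T * I(q)``.
    """

    q: np.ndarray
    y: np.ndarray
    T: float

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "T", float(self.T))
        if q.ndim != 1 or y.ndim != 1 or q.size != y.size or q.size < 1:
            raise ValueError("q and y must be 1-D arrays of equal length >= 1")
        if q[0] <= 0 or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(y < 0):
            raise ValueError("observed counts must be non-negative")
        if self.T <= 0:
            raise ValueError("pseudo-measurement time T must be positive")

    @property
    def N(self) -> int:
        return int(self.q.size)

    @property
    def grid(self) -> QGrid:
        return QGrid(self.q)

    def log_data_constant(self) -> float:
        """``ln C(D) = -sum_i ln y_i!``, the model-independent term."""
        return -float(np.sum(gammaln(self.y + 1.0)))


def poisson_cost(params: SphereMixtureParams, curve: ScatteringCurve) -> float:
    """Mean Poisson cost ``E = (1/N) sum_i (lambda_i - y_i ln lambda_i)``.

    ``lambda_i = T * I_K(q_i)`` is strictly positive because the model
    background ``B > 0``; a non-positive mean signals a broken model
    invariant and raises.
    """
    lam = curve.T * intensity(params, curve.grid)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("Poisson means must be strictly positive and finite")
    return float(np.mean(lam - xlogy(curve.y, lam)))


def log_posterior_unnorm(
    params: SphereMixtureParams,
    curve: ScatteringCurve,
    beta: float,
    priors: PriorSet,
) -> float:
    """Tempered unnormalized log posterior ``-beta N E + ln phi(params)``.

    At ``beta = 0`` this is exactly the log prior density; at ``beta = 1``
    it is the log posterior up to the data-only constant ``ln C(D)`` and the
    (model-independent) marginal likelihood.  Parameters outside the prior
    support return ``-inf`` rather than raising, so samplers can treat them
    as auto-rejected states.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("inverse temperature beta must lie in [0, 1]")
    lp = log_prior(params, priors)
    if lp == -np.inf:
        return -np.inf
    return -beta * curve.N * poisson_cost(params, curve) + lp
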