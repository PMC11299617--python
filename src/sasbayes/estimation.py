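"""Point estimates, residuals and posterior fit envelopes.

The MAP estimate is read off the retained ``beta = 1`` trace (the sample
maximizing the unnormalized log posterior ``-N E + ln phi``); residuals are
Poisson-standardized, ``(y - lambda) / sqrt(lambda)``, matching the count
noise model so that a correct fit gives residuals of mean ~0 and variance
~1; and fit-curve envelopes are built from randomly chosen posterior
samples, their per-q spread reflecting the confidence in the fitted curve.
"""

from __future__ import annotations

import numpy as np

from .likelihood import ScatteringCurve
from .models import QGrid, SphereMixtureParams, intensity
from .remc import ReplicaChain

__all__ = ["map_estimate", "residuals", "posterior_curve_envelope"]


def map_estimate(chain: ReplicaChain) -> SphereMixtureParams:
    """Maximum a posteriori parameters from the beta = 1 trace.

    Returns the retained posterior sample maximizing
    ``-N * E + ln phi``; ties are broken by the earliest sweep index.
    """
    if chain.n_samples < 1 or chain.theta.shape[0] < 1:
        raise ValueError("empty trace")
    score = -chain.N * chain.energy[:, -1] + chain.log_prior[:, -1]
    idx = int(np.argmax(score))  # argmax returns the first maximal index
    return chain.params_at(idx, l=-1)


def residuals(params: SphereMixtureParams, curve: ScatteringCurve) -> np.ndarray:
    """Poisson-standardized residuals ``(y - T I) / sqrt(T I)`` per point."""
    lam = curve.T * intensity(params, curve.grid)
    return (curve.y - lam) / np.sqrt(lam)


def posterior_curve_envelope(
    chain: ReplicaChain,
    grid: QGrid,
    n_draws: int = 1000,
    seed=0,
    quantiles=(0.05, 0.5, 0.95),
) -> dict:
    """Model curves at posterior samples, with per-q quantile bands.

    ``n_draws`` parameter vectors are drawn uniformly without replacement
    from the beta = 1 trace; the spread of the resulting curves is the
    pointwise credible envelope of the fit.

    Returns a dict with ``curves`` (n_draws, N), ``quantiles`` and the
    matching ``bands`` (len(quantiles), N).
    """
    n = chain.theta.shape[0]
    if n_draws > n:
        raise ValueError(f"n_draws={n_draws} exceeds trace length {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_draws, replace=False)
    curves = np.empty((n_draws, grid.N))
    for row, i in enumerate(idx):
        curves[row] = intensity(chain.params_at(int(i), l=-1), grid)
    bands = np.quantile(curves, quantiles, axis=0)
    return {"curves": curves, "quantiles": tuple(quantiles), "bands": bands, "indices": idx}
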