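"""Conventional reduced-chi-squared model selection (baseline).

The classical recipe: minimize chi-squared for each candidate K, divide by
the degrees of freedom ``N - (2K + 1)``, and pick the model whose reduced
chi-squared is closest to 1.  Because quasi-Newton fits of multi-sphere
models are prone to local minima, the minimization here reuses the
retained posterior samples of each candidate's REMC run, taking the sample
with the smallest chi-squared.

Chi-squared uses Pearson weighting with the Poisson variance (denominator
= model mean), consistent with the count noise model and with the
standardized residuals; a data-weighted variant (denominator
``max(y, 1)``) is available for robustness studies.
"""

from __future__ import annotations

import numpy as np

from .likelihood import ScatteringCurve
from .models import SphereMixtureParams, intensity
from .remc import ReplicaChain

__all__ = ["chi_squared", "reduced_chi_squared", "select_by_chi2"]


def chi_squared(
    params: SphereMixtureParams,
    curve: ScatteringCurve,
    weighting: str = "model",
) -> float:
    """Pearson chi-squared ``sum_i (y_i - T I_i)^2 / w_i``.

    ``weighting="model"`` (default) uses ``w_i = T I_i`` (Poisson variance
    under the model); ``weighting="data"`` uses ``w_i = max(y_i, 1)``.
    Equals the sum of squared standardized residuals under the default
    weighting.
    """
    lam = curve.T * intensity(params, curve.grid)
    if weighting == "model":
        w = lam
    elif weighting == "data":
        w = np.maximum(curve.y, 1.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.sum((curve.y - lam) ** 2 / w))


def reduced_chi_squared(chi2: float, N: int, K: int) -> float:
    """``chi2 / dof`` with ``dof = N - (2K + 1)`` (2K+1 free parameters)."""
    dof = N - (2 * K + 1)
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: N={N}, K={K}")
    return chi2 / dof


def select_by_chi2(
    chains: dict[int, ReplicaChain],
    curve: ScatteringCurve,
) -> tuple[int, dict[int, float]]:
    """Baseline selection across candidates by reduced chi-squared.

    For each candidate K, chi-squared is minimized over the retained
    beta = 1 posterior samples; the winner is the K whose reduced
    chi-squared lies closest to 1, ties broken by the smaller K.

    Returns ``(selected_K, {K: reduced_chi2})``.
    """
    red = {}
    for K, chain in sorted(chains.items()):
        chi2_min = float(chain.chi2.min())
        red[K] = reduced_chi_squared(chi2_min, curve.N, K)
    best = min(red, key=lambda K: (abs(red[K] - 1.0), K))
    return best, red
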