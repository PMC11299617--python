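"""Marginal likelihood, Bayesian free energy and model probabilities.

With the ladder anchored at ``beta = 0`` (where the normalizing constant
is exactly 1), the marginal likelihood telescopes over adjacent rungs:

    ln Z(K) = sum_{l=1}^{L-1} ln < exp(-(beta_{l+1} - beta_l) * N * E) >_l ,

each expectation taken over the retained trace at ``beta_l`` and evaluated
with a max-shift (log-sum-exp) for stability — the "stepping stone"
estimator.  A thermodynamic-integration variant (trapezoid over
``<N E>_beta``) is provided as a cross-check.

The Bayesian free energy is ``F(K) = -ln Z(K)`` (stochastic complexity) and
posterior model probabilities follow by a softmax over ``-F(K)`` weighted
by the model prior.  All values exclude the data-only constant
``sum_i ln y_i!``, which is identical across candidate models and cancels
in the model probabilities; it can be added back from
``ScatteringCurve.log_data_constant``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .priors import PriorSet, log_model_prior
from .remc import ReplicaChain

__all__ = [
    "log_marginal_likelihood",
    "model_posterior",
    "evidence_mc_error",
    "ModelSelectionResult",
]


def _stepping_stone_terms(energy: np.ndarray, betas: np.ndarray, N: int) -> np.ndarray:
    """Per-rung log ratio ln Z(beta_{l+1}) / Z(beta_l), l = 0..L-2."""
    n = energy.shape[0]
    dbeta = np.diff(betas)
    terms = np.empty(dbeta.size)
    for l in range(dbeta.size):
        a = -dbeta[l] * N * energy[:, l]
        terms[l] = logsumexp(a) - np.log(n)
    return terms


def log_marginal_likelihood(
    chain: ReplicaChain, method: str = "stepping_stone"
) -> float:
    """Estimate ``ln Z(K, beta=1)`` from REMC traces.

    ``method="stepping_stone"`` (default) multiplies adjacent-rung ratios
    estimated under the lower rung; ``method="thermodynamic"`` integrates
    ``-<N E>_beta`` over the ladder by the trapezoid rule.  The ladder must
    start at exactly ``beta = 0``, which anchors the telescope at
    ``Z(0) = 1``.
    """
    betas = chain.betas
    if betas[0] != 0.0:
        raise ValueError("ladder must start at beta = 0 (telescope unanchored)")
    if method == "stepping_stone":
        return float(np.sum(_stepping_stone_terms(chain.energy, betas, chain.N)))
    if method == "thermodynamic":
        mean_ne = chain.N * chain.energy.mean(axis=0)
        return float(-np.trapezoid(mean_ne, betas))
    raise ValueError(f"unknown method {method!r}")


def model_posterior(F: np.ndarray, log_prior_K: np.ndarray) -> np.ndarray:
    """Posterior model probabilities ``P(K|D) ~ exp(-F(K)) * phi(K)``.

    Computed with a max shift, so probabilities are invariant to adding a
    common constant to every ``F`` (which is what makes the dropped
    data constant harmless).  Raises if no model has finite weight.
    """
    F = np.asarray(F, dtype=float)
    log_prior_K = np.asarray(log_prior_K, dtype=float)
    logw = -F + log_prior_K
    if not np.any(np.isfinite(logw)):
        raise ValueError("all candidate models have -inf log weight")
    logw = logw - np.max(logw[np.isfinite(logw)])
    w = np.exp(logw)
    return w / w.sum()


def evidence_mc_error(
    chain: ReplicaChain,
    n_boot: int = 200,
    block: int = 100,
    seed=0,
) -> dict:
    """Moving-block bootstrap standard error of the stepping-stone ln Z.

    Each rung's retained cost trace is resampled in contiguous blocks of
    length ``block`` (preserving short-range autocorrelation), the rung's
    log ratio recomputed, and the total SE taken as the root sum of per-rung
    variances.  Correlation between rungs induced by exchanges is neglected,
    so this is a within-rung error estimate.
    """
    energy = chain.energy
    n, L = energy.shape
    if n < block:
        raise ValueError(f"trace length {n} shorter than block {block}")
    if n_boot < 2:
        warnings.warn("n_boot < 2 gives a degenerate SE of 0", stacklevel=2)
        z = np.zeros(L - 1)
        return {"per_term_se": z, "total_se": 0.0}
    rng = np.random.default_rng(seed)
    dbeta = np.diff(chain.betas)
    nblocks = int(np.ceil(n / block))
    boot = np.empty((n_boot, L - 1))
    for b in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=nblocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        e = energy[idx]
        for l in range(L - 1):
            a = -dbeta[l] * chain.N * e[:, l]
            boot[b, l] = logsumexp(a) - np.log(n)
    per = boot.std(axis=0, ddof=1)
    return {"per_term_se": per, "total_se": float(np.sqrt(np.sum(per**2)))}


@dataclass
class ModelSelectionResult:
    """Per-candidate evidence, probabilities and point estimates.

    ``P`` sums to 1 over the candidates; ``selected_K`` is the argmax of
    ``P`` and ``chi2_selected_K`` the reduced-chi-squared baseline's choice
    (if the baseline was run).
    """

    candidates: list
    logZ: dict
    F: dict
    P: dict
    map_params: dict
    selected_K: int
    chi2_selected_K: int | None = None
    chi2_red: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: object = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "candidates": list(self.candidates),
            "per_K": {
                str(K): {
                    "logZ": self.logZ[K],
                    "F": self.F[K],
                    "P": self.P[K],
                    "MAP": {
                        "R": list(self.map_params[K].R),
                        "S": list(self.map_params[K].S),
                        "B": self.map_params[K].B,
                    },
                    "chi2_red": self.chi2_red.get(K),
                    "diagnostics": self.diagnostics.get(K, {}),
                }
                for K in self.candidates
            },
            "selected_K": self.selected_K,
            "chi2_selected_K": self.chi2_selected_K,
            "seed": self.seed,
            "config": self.config,
        }
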