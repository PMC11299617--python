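"""Prior distributions for the mixture parameters and the component count.

All continuous parameters (radii ``R_k``, scales ``S_k``, background ``B``)
get independent Gamma priors: strictly positive support, weakly
informative, and cheap to evaluate.  The component count ``K`` gets a
discrete uniform prior over a closed integer interval, ``[1, 4]`` by
default.

Default hyperparameters (calibrated on synthetic curves with the
benchmark noise levels, the rehearsal any real analysis should repeat):

* radii: Gamma(4, 5/3), mode 5 nm — nm-scale particles, with sub-nm
  radii (which the instrument q-range cannot resolve as shape) strongly
  down-weighted;
* scales: Gamma(2, 100), mode 100 — scales of order 1e2 model units,
  density vanishing at zero;
* background: Exponential with mean 10 (Gamma shape 1) — weakly
  informative across the decades a count-level background may span, so
  unresolvable flat scatter can be absorbed by ``B`` rather than forcing
  a spurious component.

Model probabilities retain an O(1) dependence on these prior volumes
(the Occam term); see the methods note.  Configurations may declare
different prior scales per pseudo-measurement time ``T``; the defaults
are T-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import SphereMixtureParams

__all__ = [
    "GammaPrior",
    "PriorSet",
    "log_prior",
    "sample_prior",
    "log_model_prior",
    "default_priors",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, scale) prior; mean = shape*scale, mode = (shape-1)*scale."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma shape and scale must be positive")

    def logpdf(self, x) -> np.ndarray:
        return stats.gamma.logpdf(x, a=self.shape, scale=self.scale)

    def pdf(self, x) -> np.ndarray:
        return stats.gamma.pdf(x, a=self.shape, scale=self.scale)

    def cdf(self, x) -> np.ndarray:
        return stats.gamma.cdf(x, a=self.shape, scale=self.scale)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class PriorSet:
    """Independent priors for a sphere-mixture model plus the K prior.

    ``K_support`` is the closed interval of candidate component counts for
    the discrete uniform model prior.
    """

    prior_R: GammaPrior = GammaPrior(shape=4.0, scale=5.0 / 3.0)
    prior_S: GammaPrior = GammaPrior(shape=2.0, scale=100.0)
    prior_B: GammaPrior = GammaPrior(shape=1.0, scale=10.0)
    K_support: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        lo, hi = self.K_support
        if lo < 0 or hi < lo:
            raise ValueError("K_support must be a non-empty interval of ints")

    @property
    def candidate_Ks(self) -> list[int]:
        lo, hi = self.K_support
        return list(range(max(lo, 1), hi + 1))


def default_priors(T: float | None = None) -> PriorSet:
    """The package-default priors.

    ``T`` is accepted so that configurations may declare per-T prior
    scales; the defaults themselves are T-independent.
    """
    return PriorSet()


def log_prior(params: SphereMixtureParams, priors: PriorSet) -> float:
    """Sum of independent Gamma log-densities over all R_k, S_k and B.

    Returns ``-inf`` for any parameter outside the positive support (no
    exception: samplers treat it as a rejected state).
    """
    theta = params.to_vector()
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        return -np.inf
    lp = float(np.sum(priors.prior_R.logpdf(params.R)))
    lp += float(np.sum(priors.prior_S.logpdf(params.S)))
    lp += float(priors.prior_B.logpdf(params.B))
    return lp


def sample_prior(
    priors: PriorSet, K: int, rng: np.random.Generator | int
) -> SphereMixtureParams:
    """Draw mixture parameters from the prior (radii sorted descending).

    ``K = 0`` draws only the background (degenerate diagnostic model).
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    R = priors.prior_R.sample(rng, size=K)
    S = priors.prior_S.sample(rng, size=K)
    B = float(priors.prior_B.sample(rng))
    if K == 0:
        return SphereMixtureParams(R=np.empty(0), S=np.empty(0), B=B)
    return SphereMixtureParams.sorted(R=R, S=S, B=B)


def log_model_prior(K: int, priors: PriorSet) -> float:
    """Discrete uniform log prior over ``K_support``; -inf outside."""
    lo, hi = priors.K_support
    if not (lo <= K <= hi):
        return -np.inf
    return -np.log(hi - lo + 1)
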