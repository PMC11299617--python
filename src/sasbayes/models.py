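"""Forward scattering-intensity models.

The workhorse model is a dilute mixture of ``K`` monodisperse-sphere
components.  For a sphere of radius ``R`` the normalized scattering
amplitude at scattering-vector magnitude ``q`` is

    Phi(x) = 3 (sin x - x cos x) / x**3,        x = q R,

with ``Phi(0) = 1``.  The mixture intensity is

    I_K(q) = sum_k  S_k * R_k**3 * Phi(q R_k)**2  +  B,

where ``S_k`` is the normalized scale of component ``k`` and ``B > 0`` a
flat background.  The ``R**3`` factor is the particle volume of the dilute
monodisperse component: physically ``I(q) = phi * (delta_rho)**2 * V *
Phi(qR)**2`` for volume fraction ``phi``, contrast ``delta_rho`` and
particle volume ``V ~ R**3``, and the scale parameter absorbs the
remaining constants, ``S ~ (3 delta_rho)**2 phi`` up to normalization.
Keeping the volume factor explicit is what gives a large sphere its
physically dominant forward scattering relative to a small one at equal
scale; it is the convention under which the package's synthetic benchmark
experiments reproduce their expected detection limits.  Because the system
is assumed dilute there is no interparticle structure factor;
polydispersity and instrument smearing are likewise out of scope.

Mixture components carry a permutation (label-switching) symmetry; the
canonical representation used throughout the package stores components
sorted by radius in non-increasing order.

A small registry maps model names to intensity callables so that other
form factors (cylinder, core-shell, ...) can plug in behind the same
contract later; only ``"sphere_mixture"`` (and the degenerate
``"constant"`` background model used for sampler validation) ship today.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereMixtureParams",
    "QGrid",
    "form_factor_sq",
    "intensity",
    "MODEL_REGISTRY",
]

# Below this |x| the closed form of Phi(x) loses digits to cancellation;
# the Taylor series is exact to double precision there.
_SERIES_CUTOFF = 1e-2


@dataclass(frozen=True)
class SphereMixtureParams:
    """Parameters of a K-component monodisperse-sphere mixture.

    Attributes
    ----------
    R : ndarray, shape (K,)
        Sphere radii in nm, sorted non-increasing.
    S : ndarray, shape (K,)
        Normalized scale (forward-scattering amplitude) of each component,
        dimensionless model units.  Physically ``S = (3 * delta_rho)**2 * phi``
        for contrast ``delta_rho`` and volume fraction ``phi``, up to the
        normalization convention adopted here.
    B : float
        Flat background intensity, same units as the model output.

    ``K = 0`` (empty mixture, background-only model) is permitted as a
    degenerate diagnostic model; it is used to validate the sampler against
    conjugate closed forms.
    """

    R: np.ndarray
    S: np.ndarray
    B: float

    def __post_init__(self) -> None:
        R = np.atleast_1d(np.asarray(self.R, dtype=float))
        S = np.atleast_1d(np.asarray(self.S, dtype=float))
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "B", float(self.B))
        if R.ndim != 1 or S.ndim != 1 or R.size != S.size:
            raise ValueError("R and S must be 1-D arrays of equal length")
        if np.any(R <= 0) or np.any(S <= 0):
            raise ValueError("all radii and scales must be strictly positive")
        if self.B <= 0:
            raise ValueError("background B must be strictly positive")
        if R.size > 1 and np.any(np.diff(R) > 0):
            raise ValueError("R must be sorted non-increasing (canonical order)")

    @property
    def K(self) -> int:
        return int(self.R.size)

    @property
    def n_params(self) -> int:
        """Number of free scalar parameters, 2K + 1."""
        return 2 * self.K + 1

    def to_vector(self) -> np.ndarray:
        """Flatten to ``[R_1..R_K, S_1..S_K, B]``."""
        return np.concatenate([self.R, self.S, [self.B]])

    @classmethod
    def from_vector(cls, theta: np.ndarray, K: int) -> "SphereMixtureParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size != 2 * K + 1:
            raise ValueError(f"expected {2 * K + 1} entries for K={K}")
        return cls(R=theta[:K], S=theta[K : 2 * K], B=theta[2 * K])

    @classmethod
    def sorted(cls, R, S, B) -> "SphereMixtureParams":
        """Build from unordered components, sorting pairs by radius desc."""
        R = np.atleast_1d(np.asarray(R, dtype=float))
        S = np.atleast_1d(np.asarray(S, dtype=float))
        order = np.argsort(-R, kind="stable")
        return cls(R=R[order], S=S[order], B=B)


@dataclass(frozen=True)
class QGrid:
    """Strictly increasing, positive scattering-vector magnitudes (nm^-1).

    ``q = 4 pi sin(theta) / lambda`` for scattering angle ``2 theta`` and
    wavelength ``lambda``; only the magnitudes are carried here.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if q[0] <= 0 or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")

    @property
    def N(self) -> int:
        return int(self.q.size)


def form_factor_sq(x) -> np.ndarray:
    """Squared sphere form-factor amplitude ``Phi(x)**2`` at ``x = q R``.

    ``Phi(x) = 3 (sin x - x cos x) / x**3`` with the removable singularity
    at ``x = 0`` evaluated by series so that ``Phi(0)**2 == 1``.  The value
    lies in ``[0, 1]`` for all ``x >= 0``.

    Parameters
    ----------
    x : float or ndarray
        Dimensionless product ``q R``; must be non-negative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("form factor argument x must be non-negative")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = x < _SERIES_CUTOFF
    xs = x[small]
    # Phi(x) = 1 - x^2/10 + x^4/280 - ...
    out[small] = (1.0 - xs**2 / 10.0 + xs**4 / 280.0) ** 2
    xl = x[~small]
    phi = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    out[~small] = phi * phi
    return out[0] if scalar else out


def intensity(params: SphereMixtureParams, grid: QGrid) -> np.ndarray:
    """Mixture intensity ``I_K(q) = sum_k S_k R_k^3 Phi(q R_k)^2 + B``.

    Returns a vector of ``grid.N`` intensities, bounded below by ``B``.
    """
    q = grid.q
    out = np.full(q.shape, params.B, dtype=float)
    for Rk, Sk in zip(params.R, params.S):
        out += Sk * Rk**3 * form_factor_sq(q * Rk)
    return out


def _constant_intensity(params: SphereMixtureParams, grid: QGrid) -> np.ndarray:
    """Background-only model: I(q) = B.  Diagnostic / validation model."""
    return np.full(grid.q.shape, params.B, dtype=float)


#: Registry of forward models by name.  Each entry maps ``(params, grid)``
#: to a strictly positive intensity vector.  New form factors register here.
MODEL_REGISTRY = {
    "sphere_mixture": intensity,
    "constant": _constant_intensity,
}
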