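"""Synthetic scattering-curve generation and benchmark scenario grids.

Curves are generated exactly the way the numerical experiments define
them: (i) an equally spaced q grid of ``N = 400`` points on
``[0.1, 3] nm^-1``; (ii) true parameters for a two-component sphere
mixture; (iii) the noiseless model intensity scaled by a pseudo-
measurement time ``T``; (iv) independent Poisson draws per point with
those means.

Two standard scenario grids are provided:

* a **scale-ratio sweep**: spheres of radii 2 and 10 nm, the small
  sphere's scale fixed at 250 while the large sphere's scale runs through
  {250, 100, 20, 0.5, 0.1, 0.05} (scale ratios r_S = S_2/S_1 from 1.0 down
  to 0.0002), B = 0.01, at T = 1 and T = 0.1;
* a **radius-ratio sweep**: scales fixed at (250, 100), the second radius
  at 10 nm, the first running through {9.9, 9.7, 9.5, 5, 0.5, 0.4, 0.3}
  (radius ratios r_R = R_1/R_2 from 0.99 down to 0.03), at T = 1 and 0.1.

Each scenario carries an explicit list of data seeds (0..9 by default) so
replicate datasets are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import ScatteringCurve
from .models import QGrid, SphereMixtureParams, intensity

__all__ = [
    "Scenario",
    "make_qgrid",
    "generate_curve",
    "scale_ratio_scenarios",
    "radius_ratio_scenarios",
]

#: Default data seeds: ten replicate datasets per scenario.
DEFAULT_SEEDS = tuple(range(10))

# Scale-ratio sweep constants
_SCALE_R = (2.0, 10.0)          # sphere radii (nm): sphere 1 small, sphere 2 large
_SCALE_S1 = 250.0               # fixed scale of sphere 1
_SCALE_S2 = (250.0, 100.0, 20.0, 0.5, 0.1, 0.05)   # swept scale of sphere 2

# Radius-ratio sweep constants.  The first-sphere radius 5 nm fills the
# r_R = 0.5 grid point between the near-1 and near-0 regimes.
_RADIUS_R1 = (9.9, 9.7, 9.5, 5.0, 0.5, 0.4, 0.3)
_RADIUS_R2 = 10.0
_RADIUS_S = (250.0, 100.0)

_B = 0.01
_TIMES = (1.0, 0.1)


@dataclass(frozen=True)
class Scenario:
    """True data-generating conditions for one synthetic experiment.

    Spheres are stored in generation order (sphere 1, sphere 2), with
    sphere 2 the larger one in the standard grids; ``r_S = S2/S1`` and
    ``r_R = R1/R2`` follow that convention.
    """

    R1: float
    S1: float
    R2: float
    S2: float
    B: float
    T: float
    N: int = 400
    qmin: float = 0.1
    qmax: float = 3.0
    seeds: tuple = DEFAULT_SEEDS
    label: str = ""

    @property
    def r_S(self) -> float:
        """Scale ratio S2/S1 of the two generating spheres."""
        return self.S2 / self.S1

    @property
    def r_R(self) -> float:
        """Radius ratio R1/R2 of the two generating spheres."""
        return self.R1 / self.R2

    @property
    def true_params(self) -> SphereMixtureParams:
        """True K = 2 parameters in canonical (radius-descending) order."""
        return SphereMixtureParams.sorted(
            R=[self.R1, self.R2], S=[self.S1, self.S2], B=self.B
        )

    @property
    def grid(self) -> QGrid:
        return make_qgrid(self.N, self.qmin, self.qmax)


def make_qgrid(N: int = 400, qmin: float = 0.1, qmax: float = 3.0) -> QGrid:
    """N equally spaced scattering-vector magnitudes, endpoints included."""
    if N < 2:
        raise ValueError("need at least 2 grid points")
    return QGrid(np.linspace(qmin, qmax, N))


def generate_curve(scenario: Scenario, seed: int) -> ScatteringCurve:
    """Poisson-sample one synthetic curve from the scenario's true model.

    ``y_i ~ Poisson(T * I_2(q_i))`` independently per point; deterministic
    for a given seed.
    """
    grid = scenario.grid
    lam = scenario.T * intensity(scenario.true_params, grid)
    rng = np.random.default_rng(seed)
    y = rng.poisson(lam).astype(float)
    return ScatteringCurve(q=grid.q, y=y, T=scenario.T)


def scale_ratio_scenarios(times=_TIMES) -> list[Scenario]:
    """The scale-ratio sweep grid (6 ratios x len(times) noise levels)."""
    out = []
    for T in times:
        for S2 in _SCALE_S2:
            sc = Scenario(
                R1=_SCALE_R[0], S1=_SCALE_S1, R2=_SCALE_R[1], S2=S2, B=_B, T=T,
                label=f"rS={S2 / _SCALE_S1:g}_T={T:g}",
            )
            out.append(sc)
    return out


def radius_ratio_scenarios(times=_TIMES) -> list[Scenario]:
    """The radius-ratio sweep grid (7 ratios x len(times) noise levels)."""
    out = []
    for T in times:
        for R1 in _RADIUS_R1:
            sc = Scenario(
                R1=R1, S1=_RADIUS_S[0], R2=_RADIUS_R2, S2=_RADIUS_S[1], B=_B, T=T,
                label=f"rR={R1 / _RADIUS_R2:g}_T={T:g}",
            )
            out.append(sc)
    return out
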