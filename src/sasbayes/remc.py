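"""Replica-exchange Monte Carlo (parallel tempering) over a beta ladder.

A ladder of inverse temperatures ``0 = beta_1 < ... < beta_L = 1`` tempers
the Poisson likelihood: each replica targets

    pi_l(params)  propto  exp(-beta_l * N * E(params)) * phi(params),

so the coldest replica (``beta = 0``) samples the prior and the hottest
(``beta = 1``) the posterior.  Within each replica every scalar parameter
is updated by a Metropolis step with a symmetric additive proposal in log
space (the log-normal Jacobian enters the acceptance ratio, keeping the
parameters positive without boundary rejections); adjacent replicas
periodically attempt state swaps whose acceptance depends only on the cost
difference.  Mixture component labels wander freely inside the chain (the
priors are iid across components, so the unordered parameterization is
exchangeable); the canonical radius-descending order is applied when
recording traces and reporting parameters.  Re-sorting the state after
each accepted move would break detailed balance of the sequential-scan
per-site kernels — a crossing move by the "max" site can only be reversed
by the "min" site — so canonicalization is strictly an output operation.

Step sizes are adapted toward a target Metropolis acceptance rate during
burn-in only and frozen before the retained phase, preserving detailed
balance of the samples actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .likelihood import ScatteringCurve, poisson_cost
from .models import SphereMixtureParams, form_factor_sq
from .priors import PriorSet, log_prior, sample_prior

__all__ = [
    "TemperatureLadder",
    "geometric_ladder",
    "SamplerState",
    "ReplicaChain",
    "init_state",
    "metropolis_sweep",
    "exchange_step",
    "tune_step_sizes",
    "run_remc",
]

# Form-factor table resolution.  Linear interpolation error is
# O(h^2/8 * |d2(Phi^2)/dx2|) <= ~1e-9 absolute at h = 1e-4 (checked in the
# test suite); radii with q_max * R beyond the table fall back to exact
# evaluation inside the kernel.
_TABLE_H = 1e-4
_TABLE_RMAX = 120.0
# tables are pure functions of (xlim, h): share across runs on the same grid
_TABLE_CACHE: dict = {}


def _phi2_table(xlim: float, h: float) -> np.ndarray:
    key = (round(xlim, 9), h)
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = _kernel.build_phi2_table(xlim, h)
        _TABLE_CACHE.clear()  # keep at most one table resident
        _TABLE_CACHE[key] = tab
    return tab


@dataclass(frozen=True)
class TemperatureLadder:
    """Inverse temperatures ``0 = beta_1 < beta_2 < ... < beta_L = 1``.

    The exact zero at the bottom anchors the evidence telescope
    (``Z(beta=0) = 1``); the top replica is the posterior.
    """

    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("ladder needs at least two inverse temperatures")
        if b[0] != 0.0:
            raise ValueError("ladder must start at beta = 0")
        if b[-1] != 1.0:
            raise ValueError("ladder must end at beta = 1")
        if np.any(np.diff(b) <= 0):
            raise ValueError("betas must be strictly increasing")

    @property
    def L(self) -> int:
        return int(self.betas.size)


def geometric_ladder(L: int = 32, N: int | None = None, beta_min: float | None = None) -> TemperatureLadder:
    """Geometric ladder ``{0, beta_min, ..., 1}`` with L rungs.

    Geometric spacing roughly equalizes neighbor exchange rates when the
    tempered cost fluctuations scale like ``1/beta``.  The smallest positive
    rung defaults to ``1e-6 / N`` so that the first telescope factor is
    numerically indistinguishable from 1 for any realistic prior cost.
    """
    if L < 2:
        raise ValueError("need at least 2 rungs")
    if beta_min is None:
        beta_min = 1e-6 / (N if N else 100)
    if not 0 < beta_min < 1:
        raise ValueError("beta_min must lie in (0, 1)")
    body = np.geomspace(beta_min, 1.0, L - 1)
    return TemperatureLadder(np.concatenate([[0.0], body]))


@dataclass
class SamplerState:
    """Mutable per-replica sampler state plus cached model quantities.

    Data points are stored internally in a permuted order (all ``y > 0``
    first) to keep the cost reduction branch-free; the permutation is
    irrelevant to every quantity the sampler reports (cost, chi-squared and
    parameter values are permutation invariant).
    """

    betas: np.ndarray
    K: int
    # per-replica parameter arrays
    R: np.ndarray      # (L, K)
    S: np.ndarray      # (L, K)
    Bv: np.ndarray     # (L,)
    C: np.ndarray      # (L, K, N) component intensities S_k R_k^3 Phi^2(q R_k)
    I: np.ndarray      # (L, N) total model intensity
    E: np.ndarray      # (L,) mean Poisson cost
    LPRI: np.ndarray   # (L,) log prior density
    # permuted data
    q: np.ndarray
    y: np.ndarray
    npos: int
    sy: float
    T: float
    N: int
    # form-factor table
    tab: np.ndarray
    inv_h: float
    xlim: float
    qmax: float
    # prior hyperparameters
    prior_consts: tuple
    # adaptive step sizes (log-space std dev), counters
    steps: np.ndarray  # (L, P)
    acc: np.ndarray
    att: np.ndarray
    eacc: np.ndarray
    eatt: np.ndarray
    # scratch
    buf: np.ndarray
    cnew: np.ndarray
    exchange_parity: int = 0

    @property
    def L(self) -> int:
        return int(self.betas.size)

    @property
    def P(self) -> int:
        return 2 * self.K + 1

    def params(self, l: int) -> SphereMixtureParams:
        """Current parameters of replica ``l``, canonically sorted."""
        if self.K == 0:
            return SphereMixtureParams(R=np.empty(0), S=np.empty(0), B=float(self.Bv[l]))
        return SphereMixtureParams.sorted(
            R=self.R[l].copy(), S=self.S[l].copy(), B=float(self.Bv[l])
        )


def init_state(
    curve: ScatteringCurve,
    K: int,
    priors: PriorSet,
    ladder: TemperatureLadder,
    rng: np.random.Generator,
    initial_step: float = 0.5,
) -> SamplerState:
    """Initialize every replica with an independent prior draw."""
    L = ladder.L
    N = curve.N
    order = np.argsort(curve.y <= 0, kind="stable")  # y > 0 first
    q = np.ascontiguousarray(curve.q[order])
    y = np.ascontiguousarray(curve.y[order].astype(float))
    npos = int(np.sum(curve.y > 0))
    qmax = float(curve.q[-1])
    xlim = qmax * _TABLE_RMAX
    tab = _phi2_table(xlim, _TABLE_H)

    R = np.empty((L, K))
    S = np.empty((L, K))
    Bv = np.empty(L)
    C = np.empty((L, K, N))
    I = np.empty((L, N))
    E = np.empty(L)
    LPRI = np.empty(L)
    for l in range(L):
        p = sample_prior(priors, K, rng)
        R[l] = p.R
        S[l] = p.S
        Bv[l] = p.B
        for k in range(K):
            C[l, k] = p.S[k] * p.R[k] ** 3 * form_factor_sq(q * p.R[k])
        I[l] = C[l].sum(axis=0) + p.B
        lam = curve.T * I[l]
        E[l] = float(np.mean(lam - y * np.log(lam) * (y > 0)))
        LPRI[l] = log_prior(p, priors)

    P = 2 * K + 1
    return SamplerState(
        betas=ladder.betas.copy(),
        K=K,
        R=R, S=S, Bv=Bv, C=C, I=I, E=E, LPRI=LPRI,
        q=q, y=y, npos=npos, sy=float(y.sum()), T=curve.T, N=N,
        tab=tab, inv_h=1.0 / _TABLE_H, xlim=xlim, qmax=qmax,
        prior_consts=(
            priors.prior_R.shape, priors.prior_R.scale,
            priors.prior_S.shape, priors.prior_S.scale,
            priors.prior_B.shape, priors.prior_B.scale,
        ),
        steps=np.full((L, P), initial_step),
        acc=np.zeros((L, P), dtype=np.int64),
        att=np.zeros((L, P), dtype=np.int64),
        eacc=np.zeros(max(L - 1, 1), dtype=np.int64),
        eatt=np.zeros(max(L - 1, 1), dtype=np.int64),
        buf=np.empty(N),
        cnew=np.empty(N),
    )


def metropolis_sweep(state: SamplerState, rng: np.random.Generator) -> SamplerState:
    """One in-place Metropolis sweep over every replica and parameter."""
    L, P = state.L, state.P
    z = rng.standard_normal((L, P))
    lu = np.log(rng.random((L, P)))
    aR, sR, aS, sS, aB, sB = state.prior_consts
    _kernel._sweep(
        state.R, state.S, state.Bv, state.C, state.I, state.E, state.LPRI,
        state.betas, state.q, state.y, state.npos, state.sy, state.T,
        state.tab, state.inv_h, state.xlim, state.qmax,
        aR, sR, aS, sS, aB, sB,
        state.steps, z, lu, state.acc, state.att,
        state.buf, state.cnew,
    )
    return state

def exchange_step(state: SamplerState, rng: np.random.Generator, parity: int) -> SamplerState:
    """Attempt swaps for adjacent pairs (l, l+1) with l of the given parity."""
    if parity not in (0, 1):
        raise ValueError("parity must be 0 or 1")
    lu = np.log(rng.random(max(state.L - 1, 1)))
    _kernel._exchange(
        state.R, state.S, state.Bv, state.C, state.I, state.E, state.LPRI,
        state.betas, state.N, parity, lu, state.eacc, state.eatt,
    )
    return state


def tune_step_sizes(
    steps: np.ndarray,
    accepted: np.ndarray,
    attempted: np.ndarray,
    target: float = 0.3,
    gain: float = 0.6,
    bounds: tuple[float, float] = (1e-4, 5.0),
) -> np.ndarray:
    """Multiplicative step-size controller toward a target acceptance rate.

    ``steps_new = steps * exp(gain * (rate - target))`` element-wise, so
    acceptance above target grows the step and vice versa.  Called between
    burn-in windows only; retained sampling uses frozen steps.
    """
    att = np.maximum(attempted, 1)
    rate = accepted / att
    new = steps * np.exp(gain * (rate - target))
    return np.clip(new, bounds[0], bounds[1])


@dataclass
class ReplicaChain:
    """Retained REMC output: traces, diagnostics and run metadata.

    ``theta`` stores, for each retained sweep and replica, the flattened
    parameter vector ``[R_1..R_K, S_1..S_K, B]`` (radii non-increasing).
    ``chi2`` holds the Pearson chi-squared of the beta = 1 replica at each
    retained sweep, recorded on the fly for the baseline selector.
    """

    K: int
    betas: np.ndarray
    N: int
    T: float
    theta: np.ndarray       # (n_samples, L, 2K+1)
    energy: np.ndarray      # (n_samples, L)
    log_prior: np.ndarray   # (n_samples, L)
    chi2: np.ndarray        # (n_samples,)
    accept: np.ndarray      # (L, P)
    attempts: np.ndarray
    exch_accept: np.ndarray
    exch_attempts: np.ndarray
    step_sizes: np.ndarray
    n_burn: int
    n_samples: int
    seed: object = None

    @property
    def L(self) -> int:
        return int(self.betas.size)

    @property
    def posterior_theta(self) -> np.ndarray:
        """Parameter trace of the beta = 1 replica, shape (n_samples, P)."""
        return self.theta[:, -1, :]

    @property
    def prior_theta(self) -> np.ndarray:
        """Parameter trace of the beta = 0 replica (samples the prior)."""
        return self.theta[:, 0, :]

    def params_at(self, idx: int, l: int = -1) -> SphereMixtureParams:
        return SphereMixtureParams.from_vector(self.theta[idx, l], self.K)

    @property
    def acceptance_rates(self) -> np.ndarray:
        return self.accept / np.maximum(self.attempts, 1)

    @property
    def exchange_rates(self) -> np.ndarray:
        return self.exch_accept / np.maximum(self.exch_attempts, 1)

    def diagnostics(self) -> dict:
        return {
            "metropolis_acceptance": {
                "min": float(self.acceptance_rates.min()),
                "max": float(self.acceptance_rates.max()),
                "mean": float(self.acceptance_rates.mean()),
            },
            "exchange_acceptance": {
                "min": float(self.exchange_rates.min()),
                "max": float(self.exchange_rates.max()),
                "mean": float(self.exchange_rates.mean()),
            },
        }


def run_remc(
    curve: ScatteringCurve,
    K: int,
    priors: PriorSet,
    ladder: TemperatureLadder,
    n_burn: int,
    n_samples: int,
    exchange_interval: int = 1,
    rng_seed=0,
    adapt: bool = True,
    target_accept: float = 0.3,
    initial_step: float = 0.5,
    adapt_window: int = 250,
) -> ReplicaChain:
    """Run REMC for a fixed component count K and return retained traces.

    ``n_burn`` discarded sweeps (with step-size adaptation if ``adapt``)
    are followed by ``n_samples`` retained sweeps at frozen step sizes.
    Neighbor exchanges are attempted every ``exchange_interval`` sweeps with
    alternating parity.  Fully deterministic for a given ``rng_seed``.
    """
    if n_burn < 1 or n_samples < 1:
        raise ValueError("n_burn and n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    state = init_state(curve, K, priors, ladder, rng, initial_step=initial_step)
    L, P = state.L, state.P
    aR, sR, aS, sS, aB, sB = state.prior_consts

    th_tr = np.empty((n_samples, L, P))
    E_tr = np.empty((n_samples, L))
    LP_tr = np.empty((n_samples, L))
    chi2_tr = np.empty(n_samples)
    # zero-size dummies for unrecorded chunks
    th_d = np.empty((0, L, P))
    E_d = np.empty((0, L))
    chi2_d = np.empty(0)

    def parities_for(start: int, n: int) -> np.ndarray:
        """Exchange parity per sweep: -1 means no exchange attempted."""
        out = np.full(n, -1, dtype=np.int64)
        for s in range(n):
            g = start + s + 1
            if g % exchange_interval == 0:
                out[s] = (g // exchange_interval) % 2
        return out

    def run_phase(n_total: int, start_global: int, record: bool, adapting: bool):
        done = 0
        while done < n_total:
            n = min(adapt_window, n_total - done)
            Z = rng.standard_normal((n, L, P))
            LU = np.log(rng.random((n, L, P)))
            LUX = np.log(rng.random((n, max(L - 1, 1))))
            par = parities_for(start_global + done, n)
            if record:
                sl = slice(done, done + n)
                args_tr = (True, th_tr[sl], E_tr[sl], LP_tr[sl], chi2_tr[sl])
            else:
                args_tr = (False, th_d, E_d, E_d, chi2_d)
            _kernel._refresh_intensity(state.C, state.I, state.Bv)
            _kernel._run_chunk(
                state.R, state.S, state.Bv, state.C, state.I, state.E, state.LPRI,
                state.betas, state.q, state.y, state.npos, state.sy, state.T, state.N,
                state.tab, state.inv_h, state.xlim, state.qmax,
                aR, sR, aS, sS, aB, sB,
                state.steps, Z, LU, LUX, par,
                state.acc, state.att, state.eacc, state.eatt,
                state.buf, state.cnew,
                *args_tr,
            )
            if not np.all(np.isfinite(state.E)):
                raise RuntimeError(
                    "non-finite cost encountered; sampler state: "
                    f"E={state.E!r}, B={state.Bv!r}"
                )
            if adapting:
                state.steps = tune_step_sizes(
                    state.steps, state.acc, state.att, target=target_accept
                )
                state.acc[:] = 0
                state.att[:] = 0
            done += n

    run_phase(n_burn, 0, record=False, adapting=adapt)
    # freeze steps; reset counters so reported rates cover the retained phase
    state.acc[:] = 0
    state.att[:] = 0
    state.eacc[:] = 0
    state.eatt[:] = 0
    run_phase(n_samples, n_burn, record=True, adapting=False)

    return ReplicaChain(
        K=K,
        betas=state.betas.copy(),
        N=state.N,
        T=state.T,
        theta=th_tr,
        energy=E_tr,
        log_prior=LP_tr,
        chi2=chi2_tr,
        accept=state.acc.copy(),
        attempts=state.att.copy(),
        exch_accept=state.eacc.copy(),
        exch_attempts=state.eatt.copy(),
        step_sizes=state.steps.copy(),
        n_burn=n_burn,
        n_samples=n_samples,
        seed=rng_seed,
    )
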