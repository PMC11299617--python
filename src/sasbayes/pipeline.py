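"""End-to-end model selection: REMC per candidate K, evidence, tallies.

``run_model_selection`` is the single-curve entry point: it runs one REMC
chain per candidate component count, turns the traces into free energies
and posterior model probabilities, attaches MAP estimates and the
reduced-chi-squared baseline, and returns everything in a
``ModelSelectionResult``.  ``run_sweep`` repeats that over a scenario grid
with replicate datasets and tallies how often each K wins — the
Monte-Carlo experiment design used throughout the package's validation.

Seeding: a single integer seed deterministically derives independent
sampler streams for every (scenario, dataset, K) via
``numpy.random.SeedSequence``; data seeds are a property of the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chi2 import select_by_chi2
from .estimation import map_estimate
from .evidence import ModelSelectionResult, log_marginal_likelihood, model_posterior
from .likelihood import ScatteringCurve
from .priors import PriorSet, log_model_prior
from .remc import ReplicaChain, TemperatureLadder, geometric_ladder, run_remc
from .synthetic import Scenario, generate_curve

__all__ = ["SamplerConfig", "run_model_selection", "run_sweep"]


@dataclass(frozen=True)
class SamplerConfig:
    """REMC settings shared by every run of an experiment.

    ``n_burn = n_samples = 1e5`` with ``L = 32`` replicas is the
    full-scale setting; ``scale`` multiplies the sweep counts (e.g.
    ``scale=0.1`` for a desk-scale run).  ``beta_min = None`` defers to
    the ``1e-6 / N`` ladder anchor.
    """

    L: int = 32
    beta_min: float | None = None
    n_burn: int = 100_000
    n_samples: int = 100_000
    exchange_interval: int = 1
    target_accept: float = 0.3
    initial_step: float = 0.5
    adapt: bool = True
    scale: float = 1.0

    @property
    def burn(self) -> int:
        return max(1, int(self.n_burn * self.scale))

    @property
    def samples(self) -> int:
        return max(1, int(self.n_samples * self.scale))

    def ladder(self, N: int) -> TemperatureLadder:
        return geometric_ladder(self.L, N=N, beta_min=self.beta_min)

    def to_dict(self) -> dict:
        return asdict(self)


def _spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


def run_model_selection(
    curve: ScatteringCurve,
    candidate_Ks=None,
    priors: PriorSet | None = None,
    config: SamplerConfig | None = None,
    seed=0,
    keep_chains: bool = False,
    run_chi2_baseline: bool = True,
) -> ModelSelectionResult:
    """Bayesian model selection over candidate component counts.

    Runs REMC per K, estimates ``ln Z(K)`` by stepping stone, converts to
    free energies and posterior probabilities under the discrete-uniform
    model prior, and attaches the per-K MAP estimate plus the
    reduced-chi-squared baseline choice.  Fully deterministic per seed.
    """
    priors = priors or PriorSet()
    config = config or SamplerConfig()
    Ks = list(candidate_Ks) if candidate_Ks is not None else priors.candidate_Ks
    if not Ks:
        raise ValueError("candidate_Ks must be non-empty")

    ladder = config.ladder(curve.N)
    chains: dict[int, ReplicaChain] = {}
    logZ, F, mapp, diag = {}, {}, {}, {}
    for K, ss in zip(Ks, _spawn_seeds(seed, len(Ks))):
        chain = run_remc(
            curve, K, priors, ladder,
            n_burn=config.burn, n_samples=config.samples,
            exchange_interval=config.exchange_interval,
            rng_seed=ss,
            adapt=config.adapt,
            target_accept=config.target_accept,
            initial_step=config.initial_step,
        )
        chains[K] = chain
        logZ[K] = log_marginal_likelihood(chain)
        F[K] = -logZ[K]
        mapp[K] = map_estimate(chain)
        diag[K] = chain.diagnostics()

    Fv = np.array([F[K] for K in Ks])
    lpK = np.array([log_model_prior(K, priors) for K in Ks])
    P = model_posterior(Fv, lpK)
    selected = Ks[int(np.argmax(P))]

    chi2_K, chi2_red = (None, {})
    if run_chi2_baseline:
        chi2_K, chi2_red = select_by_chi2(chains, curve)

    result = ModelSelectionResult(
        candidates=Ks,
        logZ=logZ,
        F=F,
        P={K: float(p) for K, p in zip(Ks, P)},
        map_params=mapp,
        selected_K=selected,
        chi2_selected_K=chi2_K,
        chi2_red=chi2_red,
        diagnostics=diag,
        seed=seed,
        config=config.to_dict(),
    )
    if keep_chains:
        result.diagnostics["_chains"] = chains
    return result


def run_sweep(
    scenarios: list[Scenario],
    priors: PriorSet | None = None,
    config: SamplerConfig | None = None,
    candidate_Ks=None,
    base_seed=0,
    n_datasets: int | None = None,
    run_chi2_baseline: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Tally model-selection outcomes over a scenario grid.

    For each scenario and each of its data seeds (optionally truncated to
    ``n_datasets``), a curve is generated and ``run_model_selection`` is
    applied; the returned frame has one row per scenario with the number of
    datasets won by each K (Bayesian and chi-squared baseline) plus
    mean/min/max posterior probability per K.  Rows always sum to the
    number of datasets; failed runs raise rather than being dropped.
    """
    priors = priors or PriorSet()
    config = config or SamplerConfig()
    rows = []
    scen_seeds = _spawn_seeds(base_seed, len(scenarios))
    for scenario, scen_ss in zip(scenarios, scen_seeds):
        seeds = scenario.seeds[:n_datasets] if n_datasets else scenario.seeds
        Ks = list(candidate_Ks) if candidate_Ks is not None else priors.candidate_Ks
        wins = {K: 0 for K in Ks}
        chi2_wins = {K: 0 for K in Ks}
        probs = {K: [] for K in Ks}
        for data_seed, run_ss in zip(seeds, scen_ss.spawn(len(seeds))):
            curve = generate_curve(scenario, data_seed)
            res = run_model_selection(
                curve, Ks, priors, config, seed=run_ss,
                run_chi2_baseline=run_chi2_baseline,
            )
            wins[res.selected_K] += 1
            if res.chi2_selected_K is not None:
                chi2_wins[res.chi2_selected_K] += 1
            for K in Ks:
                probs[K].append(res.P[K])
            if progress:
                print(
                    f"[{scenario.label}] seed={data_seed} -> K={res.selected_K}"
                    + (f" (chi2: K={res.chi2_selected_K})" if run_chi2_baseline else ""),
                    flush=True,
                )
        row = {
            "label": scenario.label,
            "r_S": scenario.r_S,
            "r_R": scenario.r_R,
            "T": scenario.T,
            "n_datasets": len(seeds),
        }
        for K in Ks:
            row[f"wins_K{K}"] = wins[K]
        if run_chi2_baseline:
            for K in Ks:
                row[f"chi2_wins_K{K}"] = chi2_wins[K]
        for K in Ks:
            arr = np.array(probs[K])
            row[f"P{K}_mean"] = arr.mean()
            row[f"P{K}_min"] = arr.min()
            row[f"P{K}_max"] = arr.max()
        rows.append(row)
    return pd.DataFrame(rows)
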