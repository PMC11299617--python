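# sasbayes

Quantitative Bayesian model selection for small-angle scattering (SAS)
curves.

## The problem

Analyzing a SAXS/SANS curve starts with choosing a structural model —
how many particle species, what shape — before any parameter can be
fitted.  That choice is usually made by eye or by comparing fit quality
(reduced χ²) across candidates, which overfits: extra components chase
noise, and the resulting "best" model overstates the structure in the
sample.  `sasbayes` instead treats the candidate set probabilistically
and reports, for count-type intensity data, the posterior probability of
each candidate model together with Bayesian estimates of its parameters
and a quantitative confidence for the selection.

## Model and method

Measured intensities are photon counts, modelled per point as

    y_i ~ Poisson(T · I_K(q_i)),

with pseudo-measurement time `T` (count scale; smaller T = noisier) and,
for a dilute mixture of K monodisperse spheres,

    I_K(q) = Σ_k S_k R_k³ Φ(qR_k)² + B,     Φ(x) = 3(sin x − x cos x)/x³,

with radii `R_k` (nm), normalized scales `S_k`, background `B`, and the
particle-volume factor `R³` of each dilute component.  With Gamma priors
φ(Ξ) on the parameters and a uniform prior over candidate K, the
evidence

    Z(K) = ∫ p(D|Ξ,K) φ(Ξ|K) dΞ,     F(K) = −ln Z(K)

is computed by replica-exchange Monte Carlo over an inverse-temperature
ladder 0 = β₁ < … < β_L = 1 (the tempered posteriors
∝ exp(−βNE)·φ), using the stepping-stone telescope

    ln Z(K) = Σ_l ln ⟨ exp(−(β_{l+1}−β_l) N E) ⟩_{β_l},

where `E = (1/N) Σ_i (λ_i − y_i ln λ_i)` is the mean Poisson cost.
Posterior model probabilities follow as the softmax
P(K|D) ∝ exp(−F(K))·φ(K); the β = 1 trace simultaneously yields MAP
parameters, credible intervals, fit envelopes and standardized
residuals.  A conventional reduced-χ² selector (Pearson χ² minimized
over the posterior samples, dof = N − (2K+1), winner closest to 1) is
included as the baseline it is meant to replace.  See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a two-sphere specimen (R = 10 and 2 nm, equal scales 250,
B = 0.01, T = 1) and ask which of K = 1..4 component models the data
support:

```python
import sasbayes as sb
from sasbayes.synthetic import Scenario, generate_curve
from sasbayes.pipeline import SamplerConfig, run_model_selection

scenario = Scenario(R1=2, S1=250, R2=10, S2=250, B=0.01, T=1.0)
curve = generate_curve(scenario, seed=0)          # 400 Poisson-noised points

config = SamplerConfig(L=24, n_burn=10_000, n_samples=10_000)
result = run_model_selection(curve, seed=0, config=config)

print(result.P)               # {1: 0.0, 2: 0.9635, 3: 0.0354, 4: 0.0011}
print(result.selected_K)      # 2
print(result.chi2_red)        # {1: 507.93, 2: 0.9872, 3: 0.992, 4: 0.9978}
print(result.map_params[2].R) # [10.002  2.003]
print(result.map_params[2].S) # [249.91  251.01]
```

The numbers shown are the output of this exact script.  Reading: the
two-component model carries 96% posterior probability and its MAP
estimate recovers the true radii and scales to a fraction of a percent,
while the single-sphere model is ruled out (its free energy is higher by
~9.1×10⁴ nats).  The reduced-χ² column shows why the conventional
criterion is treacherous here: K = 2, 3, 4 all sit within 2% of 1 and
the "closest to 1" rule picks K = 4 — the Occam term in the evidence is
what penalizes the unneeded components.

The same pipeline is scriptable from the shell:

```bash
sasbayes simulate --grid scale --outdir curves       # curves + truth manifest
sasbayes select curves/rS=1_T=1_seed0.dat -T 1 --seed 0 --scale 0.1
sasbayes sweep --grid radius --scale 0.1 --out tally.csv
```

`--scale 0.1` runs the sampler at a tenth of the full sweep counts for
desk-scale exploration; priors, ladder and sweep settings can be
overridden with a YAML `--config` file.

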