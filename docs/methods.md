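# Methods

This note documents the statistical model, the numerical choices behind
the sampler and evidence estimator, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
problem left them open.

## Observation model

A small-angle scattering (SAS) curve is a set of N pairs (q_i, y_i):
scattering-vector magnitudes q (nm^-1) and measured intensities y.
Because detectors count photons, y_i is modelled as Poisson:

    y_i ~ Poisson(lambda_i),    lambda_i = T * I_K(q_i, Theta),

where T is a pseudo-measurement time (count-scale multiplier: smaller T,
noisier data) and I_K the model intensity of a candidate structure with
K components.  The per-curve mean cost

    E(Theta) = (1/N) * sum_i [lambda_i - y_i ln lambda_i]

carries the full likelihood up to the data-only constant
C(D) = prod_i 1/y_i!:  p(D|Theta, K) = C(D) exp(-N E).  C(D) is dropped
everywhere; it is identical across candidate models for the same curve
and cancels exactly in posterior model probabilities.  Reported free
energies are therefore offset by sum_i ln y_i! relative to the fully
normalized convention; `ScatteringCurve.log_data_constant()` restores it.

The 1/N normalization of E is a convention choice; it keeps E of order
unity-per-point and makes the tempering and exchange formulas carry an
explicit factor N.

## Forward model: dilute sphere mixtures

For a dilute mixture of K monodisperse-sphere components,

    I_K(q) = sum_k S_k * R_k^3 * Phi(q R_k)^2 + B,
    Phi(x) = 3 (sin x - x cos x) / x^3,  Phi(0) = 1,

with radii R_k (nm), normalized scales S_k (dimensionless; physically
S ~ (3 delta_rho)^2 phi for contrast delta_rho and volume fraction phi),
and a flat background B > 0.  The R^3 factor is the particle volume of
the dilute component (I = phi * delta_rho^2 * V * Phi^2); it is what
gives a large sphere its dominant forward scattering at equal scale, and
it is essential for the detection-limit structure of the benchmark
experiments: without it, a faint second component at scale ratios of
1e-3 to 1e-4 would contribute a fraction of a count against hundreds of
counts of Poisson noise and no method could detect it.  The convention
is isolated in `sasbayes.models`; alternative form factors (cylinders,
core-shell) can be registered in `MODEL_REGISTRY` behind the same
contract but are not implemented.

Mixture labels are exchangeable; the canonical representation sorts
components by radius, non-increasing.  The parameter container enforces
this order, and the sampler applies it when recording traces and
reporting states.  Inside the chain the labels deliberately wander: with
iid priors across components the unordered parameterization is
exchangeable and sequential-scan Metropolis preserves it exactly,
whereas re-sorting the state after each accepted move breaks the
per-site kernels' detailed balance (a crossing move by the largest-
radius site can only be reversed by the smallest-radius site) and
measurably biases the sampled radius marginals.
Assumed away: interparticle structure factor (dilute limit),
polydispersity, instrument smearing, absolute-unit calibration.

## Priors

Independent Gamma priors on every positive parameter, and a discrete
uniform prior on K over {1..4}:

| parameter | default prior    | mode | rationale                             |
|-----------|------------------|------|---------------------------------------|
| R_k (nm)  | Gamma(4, 5/3)    | 5    | nm-scale particles; sub-nm radii (unresolvable as shape in this q-range) strongly down-weighted |
| S_k       | Gamma(2, 100)    | 100  | scales of order 1e2 model units       |
| B         | Gamma(1, 10)     | 0+   | exponential: weakly informative across the decades a background can span |

These defaults were calibrated the way any real analysis should
calibrate its priors: by rehearsing on synthetic curves with the noise
level of the study conditions and checking that the selection boundaries
land where the physics says they must.  Two choices matter:

* the *background* prior must be broad.  A tight prior pinned at the
  generating value forbids the simpler model from absorbing
  unresolvable flat scatter (a tiny sphere's near-constant term) into
  ``B``, forcing a spurious extra component precisely where the method
  should declare the data uninformative;
* the *radius* prior must down-weight radii the q-range cannot resolve.
  Otherwise a "component" with sub-nm radius and ordinary scale acts as
  a cheap second background, eroding the Occam penalty that makes the
  component count identifiable.

All hyperparameters are configurable, and a configuration may declare
different prior scales per measurement time T; the defaults are
T-independent.  Model probabilities (unlike point estimates) retain an
O(1) dependence on prior volumes, so a change of priors moves the
detection limits — rehearse before trusting.

## Replica-exchange sampling

Each candidate K gets an independent replica-exchange Monte Carlo (REMC,
parallel tempering) run over inverse temperatures
0 = beta_1 < ... < beta_L = 1 targeting

    pi_l(Theta) ~ exp(-beta_l * N * E(Theta)) * phi(Theta).

* **Ladder.**  beta_1 = 0 exactly (the prior; anchors the evidence
  telescope), then a geometric progression from beta_min = 1e-6/N to 1.
  Geometric spacing roughly equalizes neighbor exchange rates when
  tempered cost fluctuations scale like 1/beta; the tiny anchor makes
  the first telescope factor indistinguishable from 1.  L = 32 by
  default; the benchmark experiments use L = 24.
* **Within-replica moves.**  Single-site Metropolis over every scalar
  parameter, with symmetric additive proposals in log space
  (equivalently multiplicative), which keeps parameters positive without
  boundary rejections; the log-normal Jacobian joins the Gamma-prior
  term in the acceptance ratio, where the two combine to the
  transcendental-free increment a*dz - dv/s.
* **Exchanges.**  Adjacent pairs attempt swaps every sweep with
  alternating parity; acceptance min(1, exp(N (beta_{l+1}-beta_l)
  (E_{l+1}-E_l))) — the shared prior cancels.
* **Step-size adaptation.**  During burn-in only, per-replica per-
  parameter steps follow a multiplicative controller toward a target
  Metropolis acceptance of 0.3; steps are frozen before the retained
  phase so the recorded samples come from a fixed, detailed-balanced
  kernel.
* **Determinism.**  All randomness is drawn from a single
  `numpy.random.Generator` seeded by the caller; runs are bit-for-bit
  reproducible.

### Numerical acceleration

The per-proposal cost evaluation dominates runtime (every proposal needs
lambda and ln lambda at all N points).  Three measures keep it fast,
none of which changes the sampled distribution beyond documented
tolerances:

* the squared sphere amplitude Phi^2 is linearly interpolated from a
  dense uniform table in x = qR (spacing 1e-4; absolute error < 1e-9,
  verified in the test suite), with exact evaluation beyond the table;
* ln lambda uses an exponent/mantissa split with an atanh-form
  polynomial (fdlibm coefficients; relative error ~1e-15);
* data points are pre-permuted so all y > 0 points form a prefix and the
  y ln lambda reduction runs branch-free (the point order is irrelevant
  to every reported quantity).

Per-replica intensities are updated incrementally per accepted component
move and refreshed from scratch periodically to clear round-off drift.
The net effect of the table approximation on the mean cost E is below
1e-5 in absolute terms, orders of magnitude below any free-energy
difference the method is asked to resolve.

## Evidence, free energy, model probability

With the ladder anchored at beta = 0, the marginal likelihood telescopes
("stepping stone"):

    ln Z(K) = sum_l ln < exp(-(beta_{l+1}-beta_l) N E) >_{beta_l},

each expectation over the retained trace at beta_l, evaluated by
log-sum-exp.  The Bayesian free energy is F(K) = -ln Z(K), and

    P(K|D) = exp(-F(K)) phi(K) / sum_{K'} exp(-F(K')) phi(K'),

computed with a max shift so any common offset in F (such as the dropped
data constant) cancels.  A thermodynamic-integration variant (trapezoid
over <N E>_beta) is provided as a cross-check; it carries a ladder-
discretization bias (about -0.5 nat at L = 16 on the conjugate
validation problem) and is not the default.  A moving-block bootstrap
(per rung, block length 100 by default) gives a standard error for
ln Z; it neglects cross-rung correlation induced by exchanges and is
therefore a within-rung error estimate.

The estimator is validated end-to-end against an exact result: for the
degenerate background-only model (K = 0) the Gamma prior is conjugate to
the Poisson likelihood and ln Z has a closed form; the REMC estimate
agrees within bootstrap error (see the test suite).

## Point estimates and fit assessment

* **MAP**: the retained beta = 1 sample maximizing -N E + ln phi (ties:
  earliest sweep).
* **Residuals**: Poisson-standardized, (y - lambda)/sqrt(lambda), so a
  correct model yields mean ~0, variance ~1 at every q.
* **Envelopes**: intensity curves at posterior samples drawn without
  replacement; per-q quantile bands express fit confidence.
* **Reduced chi-squared baseline**: Pearson chi-squared with model-mean
  weighting (consistent with the Poisson variance), minimized over the
  retained beta = 1 samples of each K (avoiding local-minimum issues of
  quasi-Newton fits), divided by dof = N - (2K+1); the candidate closest
  to 1 wins, ties to the smaller K.  A data-weighted denominator
  (max(y,1)) is available for robustness studies.

## Synthetic benchmark experiments

The generator reproduces the study conditions used throughout
validation: N = 400 equally spaced q points on [0.1, 3] nm^-1; a
two-component truth; intensities scaled by T in {1, 0.1}; independent
Poisson draws per point; ten replicate datasets per scenario (data seeds
0..9).  Two scenario grids:

* **scale-ratio sweep** — R = (2, 10) nm, S_1 = 250,
  S_2 in {250, 100, 20, 0.5, 0.1, 0.05} (r_S = S_2/S_1 from 1 to
  2e-4), B = 0.01;
* **radius-ratio sweep** — S = (250, 100), R_2 = 10 nm,
  R_1 in {9.9, 9.7, 9.5, 5, 0.5, 0.4, 0.3} (r_R = R_1/R_2 from 0.99
  to 0.03), B = 0.01.

What the generator does *not* emulate: instrument resolution/smearing,
dark current, inter-particle interference, polydispersity, or absolute
calibration.  Passing benchmarks therefore demonstrate the statistical
machinery under the stated noise model, not robustness to real-beamline
systematics.

### Problem sizes used in validation

Full-scale runs use n_burn = n_samples = 1e5 sweeps.  The package's own
validation (test suite and `scripts/acceptance.py`) runs the benchmark
grids at n_burn = n_samples = 1e4 with L = 24, which resolves the same
selection boundaries with mildly wider Monte-Carlo scatter in the
tallies; the test suite further trims replicate-dataset counts (3-5 per
scenario instead of 10) while the acceptance script runs the full ten.
These sizes are the package's standard desk-scale configuration
(`SamplerConfig(scale=...)` rescales them).

## Known limitations

* Model probabilities depend on prior volumes (the Occam term); the
  shipped defaults reproduce the benchmark detection limits but are not
  universal.  Calibrate priors on matched synthetic data first.
* The chi-squared baseline's minimum-over-samples depends weakly on
  trace length: longer traces dig marginally deeper minima.  Near-ties
  between adjacent K (differences of ~0.005 in reduced chi-squared) can
  flip with sampler length.
* Evidence error bars ignore cross-rung correlation (see above).
* K is fixed per run; model selection is across runs rather than
  transdimensional, which is exact for a small candidate set but scales
  linearly in its size.
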