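# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the tests do and do not establish.

## Critical nitrogen dilution curve and NNI

The critical concentration `Nc(DM) = a·DM^(−b)` (a in %N at DM = 1 t·hm⁻², b a
positive dimensionless exponent; the exponent is *stored* positive and applied
with a negative sign) is constructed by the five-step per-day procedure
described in the README. Numerical choices:

- **Gradient partition.** One-way ANOVA on AGB across fertilization gradients
  at α = 0.05, followed by Tukey HSD of every gradient against the gradient
  with the highest mean AGB; gradients significantly *lower* are N-limited.
  If replicates are degenerate (zero pooled within-group variance, as in
  noise-free simulation), any strictly lower mean counts as limited. Without
  replicates a means-only rule applies: non-limited iff mean AGB ≥ 0.95 × the
  top gradient mean (tolerance τ = 0.05, configurable) — needed because
  published tables usually report only gradient means.
- **Power fit.** Nonlinear least squares on the concentration scale
  (`scipy.optimize.curve_fit`, positivity bounds), initialized from a log–log
  OLS. Fitting on the original scale keeps the reported RMSE in %N units and
  avoids the error re-weighting a log-scale fit would introduce. Degenerate
  inputs (fewer than two distinct-AGB limited points, non-positive predicted
  critical concentration) raise a dedicated error; the orchestrator skips such
  days with a warning.
- **Group boundary.** NNI = 1 belongs to the *rich* group (deficit is the
  strict inequality NNI < 1).
- With several experiments in one table, the curve is fitted on the first
  experiment's critical points; the other experiments' points are reported as
  validation R² diagnostics.

## Synthetic study design

The generator emulates a two-experiment rice trial: experiment 1 with N rates
{0, 75, 150, 225, 300} kg·hm⁻² and 3 plots per gradient, experiment 2 with
{0, 50, 100, 150, 200} kg·hm⁻² and 2 plots, both sampled on 8 days from
tillering to heading — 200 plot-day samples with paired agronomy records and
400–1000 nm spectra at 1 nm.

- **Biomass.** AGB grows logistically in the day index (rate 0.8/day index,
  midpoint day 4) with gradient asymptotes (3.0, 5.0, 6.5, 7.5, 7.5) t·hm⁻²;
  the top two gradients share one asymptote, producing the biomass plateau the
  partition step must find. Multiplicative lognormal noise, σ = 0.05.
- **N concentration.** The generator is built around the dilution-curve
  geometry: within each day, the N-limited gradients' concentrations lie
  (before noise) on a positive-slope line through the day's critical point
  `(AGB_plateau, Nc(AGB_plateau))` — exactly the geometry the five-step
  procedure assumes, and the within-day pattern real gradient trials show
  (N% and AGB both rise with fertilization). The slope parameter (0.5 of
  `Nc/AGB` at the plateau) spreads latent NNI over roughly 0.45–1.0 across the
  limited gradients. Plateau gradients draw latent NNI ~ U(1.0, 1.3).
  Lognormal noise σ = 0.05 multiplies the concentrations; the stored latent
  NNI is always the exact ratio `Nnc / (a·AGB^(−b))`. With noise switched off
  the five-step procedure therefore recovers (a, b) = (2.03, 0.46) to machine
  precision — the key recovery oracle of the test suite.
- **Forced standard sample.** One plateau plot per day is overwritten with an
  N concentration giving NNI ~ U(0.991, 1.009), guaranteeing the
  standard-spectrum rule is exercisable every day (the *measured* NNI, which
  uses the *fitted* curve, can still drift slightly outside the window — the
  selection then falls back to the nearest-NNI sample, flagged and logged).
- **Spectra.** Phenomenological, not radiative transfer: an AGB-driven NIR
  plateau `0.28 + 0.32(1 − e^(−AGB/4.5))` joined through a logistic red edge
  (midpoint 715 nm, width 12 nm) to a 0.05 visible baseline with a Gaussian
  green peak (550 nm), minus chlorophyll absorption wells at 660 and 430 nm
  whose depth `0.045(1 − e^(−c/4))` grows with the canopy chlorophyll proxy
  c = N% × AGB. Additive Gaussian noise (σ = 0.002 reflectance units), clipped
  to (0, 1]. The construction guarantees two strict monotonicities the tests
  assert: reflectance at 660 nm falls with N at fixed AGB, and at 800 nm rises
  with AGB at fixed N.

What the generator does **not** emulate: radiative-transfer physics, soil and
water background, within-field spatial structure, sensor artifacts, or
growth-stage-specific spectral shape changes beyond the biomass/chlorophyll
drivers. Passing tests therefore demonstrate that the pipeline recovers known
structure under its own assumptions, not field-data accuracy.

## Spectral preprocessing and transforms

Resampling to the integer-nm grid uses piecewise-linear interpolation (exact
on locally linear reflectance, no extrapolation). Denoising is a 1-D Gaussian
filter along wavelength, σ = 2 nm by default, kernel truncated at 4σ, reflect
boundary; σ = 0 is the identity. The standard-spectrum window is the open
interval (0.99, 1.01); multiple qualifiers are averaged band-wise; an empty
window falls back to the nearest-NNI sample of that day (flagged
`fallback_used`, logged). Standards are strictly per sampling period — a
sample is never differenced against another day's standard. Log transforms
demand strictly positive reflectance and raise rather than clip. Reflectance
is stored as a fraction in (0, 1]; logarithms are natural.

## Sparse autoencoder and feature selection

The classical sparse-autoencoder objective is used:

```
L = 1/(2n) Σ_i ‖x_i − x̂_i‖²  +  λ/2 Σ w²  +  β Σ_j KL(ρ ‖ ρ̂_j)
```

with sigmoid encoder and decoder, ρ = 0.1, λ = 0.001, β = 3. The
reconstruction term is summed over bands and averaged over samples — the
scaling under which this hyperparameter triple is meaningful (with a per-entry
mean the KL term would dominate a 601-band spectrum by two orders of
magnitude and collapse the representation). Training is deterministic
full-batch gradient descent, learning rate 0.01 (larger rates oscillate under
this loss scaling on 601-band inputs), seeded uniform Glorot initialization,
inputs min–max scaled per band on training rows only. Competing widths are
ranked by held-out RMSE of an OLS regression of NNI on the encoded features;
ties break to the narrower encoder. The autoencoder only ever sees training
rows; test rows are encoded, never fitted.

## ELM, BES and BES-ELM

ELM: hidden weights and biases uniform on [−1, 1] (seeded or supplied), hidden
activations sigmoid, output weights the SVD-based minimum-norm least-squares
solution. The pseudo-inverse solve is verified against an explicit SVD oracle
in the tests. Plain ELM inherits the well-known instability of random hidden
layers — occasionally ill-conditioned hidden matrices yield large output
weights and poor generalization — which is precisely the motivation for the
hybrid.

BES uses the canonical three-phase formulation. Per iteration and member:
select `P_best + α r (P_mean − P_i)` with α = 2 and r ~ U(0,1); search
`P_i + y(i)(P_i − P_{i+1}) + x(i)(P_i − P_mean)` with polar-spiral weights
x, y from θ(i) = a·π·rand (a = 10), r(i) = θ(i) + R·rand (R = 1.5), normalized
by the population maximum magnitude; swoop
`rand·P_best + x1(i)(P_i − c1 P_mean) + y1(i)(P_i − c2 P_best)` with
sinh/cosh spiral weights and c1 = c2 = 2. Acceptance is greedy (a move is kept
only if it improves that member), positions are clipped to the box after every
phase, and the iteration counter advances by one per three-phase sweep. Greedy
acceptance makes the best-fitness trace provably non-increasing — a property
the tests assert for arbitrary fitness functions.

BES-ELM searches the flattened (W, b) in [−1, 1] with fitness = validation-set
RMSE of the ELM whose output weights are solved on the training set. The
initial population includes the plain seeded ELM's (W, b) as a founder (warm
start): combined with greedy acceptance this guarantees the returned model's
validation RMSE never exceeds the paired plain ELM's, so the optimizer can
only help — the behaviour the hybrid is designed for. Output weights of the
returned model are re-solved on the training set only.

## Pipeline and evaluation

- Split: 70/30, stratified by (sampling period, NNI group) where every stratum
  has ≥ 2 samples, otherwise a seeded global split with a warning. Samples
  that define a day's standard spectrum are pinned to the training side — they
  are the transform origin of their day and would otherwise leak into the test
  set as exact zeros; the train fraction may exceed 70% slightly as a result.
- Metrics: the standard coefficient of determination 1 − SSres/SStot and
  RMSE = √(Σ(ŷ−y)²/n). Group metrics (NNI < 1 vs NNI ≥ 1, by *measured* NNI)
  are computed within each group; groups with n < 3 or zero variance are
  flagged undefined rather than reported as numbers. (An alternative printed
  form of R² as an explained-over-residual ratio is unbounded and not used.)
- The BES-ELM validation set is the held-out test set, mirroring a
  train/verification design in which the verification RMSE is the optimizer's
  fitness; reported test metrics for BES-ELM are therefore optimistically
  biased relative to a third, untouched partition, identically for every
  transform, so the transform comparison is fair.
- Default run sizes are chosen to keep a full desk run in seconds on one CPU:
  one autoencoder width (30) at 300 epochs per transform, ELM with 20 hidden
  units, BES population 12 × 20 iterations. All of these are config fields;
  widening the candidate grid (e.g. 10…60 step 5) and raising the BES budget
  uses the identical code paths, which the unit tests exercise on smaller
  matrices.
- Every stage draws its seed deterministically from the master seed (CRC-based
  sub-seeding, stable across processes); two runs with the same config are
  bit-identical.

## Known limitations

- The spectral generator's monotone, low-dimensional structure makes the
  estimation problem easier than field data; absolute R² values on synthetic
  data overstate field performance and only the *relative* orderings
  (transform comparison, BES-ELM vs ELM, deficit vs rich group) are meaningful
  claims.
- The dilution-curve procedure assumes the fertilization design actually
  produces a biomass plateau; designs where the top gradient is still
  N-limited bias the curve.
- Sigmoid decoders cannot represent values outside (0, 1); inputs are min–max
  scaled, so test-set values outside the training range reconstruct
  imperfectly.
- Full-batch gradient descent is deliberate (deterministic, dependency-free)
  but slow near convergence; reconstruction-critical uses may need more
  epochs than the pipeline default.
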