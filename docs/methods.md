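# Methods

This note documents the generative model, the inference machinery, the
synthetic study design, and the numerical and design choices behind them.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Neuronal model

Regional activity `z` (4 regions: OCC, FG, IPS, IFG) evolves as
`dz/dt = (A + Σ_j u_j B^j) z + C u`.  Conventions:

- **Index order**: row = target, column = source.  `A[t, s]` is the rate
  (Hz) at which activity in source `s` changes activity in target `t`.
  Literature that writes "A_{i,j}, from area i to area j" uses the
  transpose of this layout; the serialisation header repeats this warning.
- **Self-connections** are log-scaled: the effective diagonal is
  `-0.5·exp(a_self + Σ_j u_j b_self^j)` Hz.  Estimation can therefore
  weaken or strengthen self-inhibition but never make it excitatory; a
  *negative* vividness self-modulation of OCC implements the
  "disinhibition with more vivid imagery" mechanism.
- **Inputs**: a perception boxcar (on during both 2 s stimulus
  presentations), an imagery boxcar (on during the 3.5 s imagery frame),
  and a vividness parametric input equal to the per-category mean-centred
  1–4 rating during the frame and zero elsewhere.  Modulatory inputs are
  not mean-centred by default, so `A` is coupling in the absence of
  stimulation; a flag in `build_input_regressors`/`effective_connectivity`
  callers can centre them, which redefines `A` as session-average coupling.

Integration is exact per microtime bin (default `dt = 0.1 s`): inputs are
piecewise constant, so the state map over a bin is the augmented-matrix
exponential `expm([[E·dt, Cu·dt], [0, 0]])`, which also yields the forced
response without solving a linear system.  A compiled recursion applies the
per-unique-input propagators over the session.

### Stability guard

Accepted parameter sets must satisfy `max Re eig(A + Σ_j u_j B^j) < 0` at
every *realisable* input combination.  For the canonical paradigm these are
baseline, perception-only, and imagery with vividness anywhere in ±2.1
(perception and imagery boxcars never overlap, and a mean-centred 1–4
rating cannot leave that interval); during integration the check runs on
the actual unique input rows.  A rectified worst case (`A + Σ|B^j|`) is
deliberately **not** used: with a 0.94 Hz perception-on coupling it
rectifies the stabilising inhibitory feedback (IPS→OCC is inhibitory while
OCC→IPS is strongly excitatory) into spurious positive loops and rejects
essentially every realistic parameter set, including the preset itself.

## Haemodynamic model

Per region, the four-state balloon/Windkessel cascade (vasodilatory signal,
inflow, venous volume, deoxyhaemoglobin) with canonical constants: signal
decay 0.64 s⁻¹, flow feedback 0.32 s⁻¹, transit time 2.0 s, Grubb exponent
0.32, resting oxygen extraction 0.4, neurovascular efficacy 1, and the
classic nonlinear read-out `y = 100·V0·(k1(1−q) + k2(1−q/v) + k3(1−v))`
with `V0 = 0.04`, `k1 = 7E0`, `k2 = 2`, `k3 = 2E0 − 0.2` (percent signal
change).  States are integrated by RK4 on the microtime grid with the
neuronal drive frozen per bin; transit time and decay are estimable as
per-region log-scalings.  Scans are linear interpolations of the
continuous signal at `(k + slice_offset)·TR`, `slice_offset = 0.5` by
default; observation noise is i.i.d. Gaussian (no serial correlation
model — first-level autocorrelation handling is out of scope).

## Variational Laplace

The per-subject posterior is Gaussian, updated by Gauss–Newton ascent on
the Laplace free energy with Levenberg-style damping (rejected steps double
the regulariser, up to 10 per iteration; accepted free energies are
non-decreasing by construction).  Sensitivities are one-sided finite
differences with relative step `1e-4`, computed for all parameters in one
batched forward pass.  Observation noise enters through a single
log-precision hyperparameter (prior `N(0, 1)`, i.e. unit noise sd a
priori), conditionally maximised by Newton steps between parameter updates;
its Laplace variance contributes a KL term to `F`.  With the noise
precision fixed and a linear forward map the scheme is exact: `F` equals
the log marginal likelihood and the posterior the conjugate solution
(asserted to 1e-6/1e-4 in the tests).

Defaults: tolerance `1e-4` nats, 128 iterations.  The multi-subject
pipeline runs at tolerance `1e-3` and 96 iterations, which on the
calibration problems terminates at the same optima in roughly half the
time (one subject inverts in ~5 s on one core).

**Priors** (all configurable): between-region `A`, `B` entries `N(0, 1/16)`
Hz — sd 0.25, weakly informative for the sub-hertz couplings this level of
modelling produces; driving `C` entries `N(0, 1)`; self-connection
log-scalings `N(0, 1/16)`; haemodynamic log-scalings `N(0, 1/256)`.
Tighter conventional tables (e.g. variance 1/64 on coupling entries) were
evaluated during development and shrink strong modulations by 30–60% even
at low noise, with compensatory distortion of the remaining parameters;
the wider defaults satisfy the package's recovery requirement (≥ 90% of
free parameters within 2 posterior sd at SNR ≈ 1, tested).

**Known limitation — multimodality at low SNR.**  At the calibration noise
level the per-subject free energy is multimodal: for a minority of noise
realisations the ascent from the prior mean terminates in a basin that
underestimates the strongest modulatory coupling, and the group estimate of
the perception-on OCC→IPS total then lands 10–25% below the generating
value.  Multi-start, staged, hot-precision and homotopy variants were
evaluated and do not reliably cross the (several-hundred-nat) barrier;
PEB-guided re-inversion raises the subject posteriors but the empirical
prior it introduces absorbs the gain at the group level.  The shipped
scheme is the plain single-start ascent; the group-level 2-sd credible
band covers the truth in most replicates.

## Bayesian model reduction, families, BMA

"Switching a parameter off" clamps its prior variance to `1e-8` (kept
finite so precisions exist; configurable).  Reduced posteriors and
evidence changes use the closed-form Gaussian identity in precision form;
the implementation is validated against direct inversion of the reduced
model and against 1-D numerical quadrature.  Model spaces over `k`
switchable parameters are exhaustive for `k ≤ 16` and greedy beyond
(repeatedly remove the parameter whose clamping most increases evidence,
retaining every evaluated model in the space; flagged non-exhaustive).
Family probabilities use a flat model prior and log-sum-exp; `Pp` of a
parameter is the evidence mass of the models containing it.  BMA is the
moment-matched Gaussian of the evidence-weighted mixture over the best 256
models (weights beyond that are numerically negligible).

## Parametric empirical Bayes

The group model is `θ_i = (x_i ⊗ I)β + b_i`, `b_i ~ N(0, e^{-γ}·D)` with
`D = I/16` and `γ ~ N(0, 1/16)`.  Each subject's first-level posterior
enters as a likelihood after its first-level prior is removed in
information form (the subtraction is floored at zero precision, and
information components in flattened directions are zeroed so uninformed
parameters carry no weight).  Conditional on `γ` the model is
linear-Gaussian in `β` and solved exactly; `γ` is maximised by bounded
scalar search.  The default group prior per effect reuses that parameter's
first-level prior variance, which makes the single-subject hierarchy
collapse to the subject's own posterior — a tested invariant.  Group-level
reduction switches only the condition-specific (`B`) effects; baseline
`A` effects stay in the model, as the scientific questions concern
condition-induced changes.

## Pooled directional contrasts

Bottom-up = {OCC→FG, OCC→IPS, OCC→IFG, FG→IFG, IPS→IFG}; top-down =
{FG→OCC, IPS→OCC, IFG→OCC, IFG→FG, IFG→IPS}.  The two lateral FG↔IPS
connections belong to neither set by this definition and are excluded from
both.  The pooled quantity per condition is the equally weighted (1/5)
mean of the corresponding `B` entries of the BMA group posterior (a
summed variant is available); its posterior is the exact Gaussian of the
linear functional, `Pp(>0)` its upper tail at zero, and condition
comparisons use the difference functional within the same posterior — all
cross-checked against Monte-Carlo sampling.  The tail-probability reading
of the pooled comparison is used throughout; a model-family reading of the
same question would be a different statistic.

## Synthetic studies

`paper_ground_truth()` loads the versioned preset
(`presets/visual_imagery.json`).  Text-anchored entries: baseline OCC→IPS
0.05 Hz; perception-on OCC→IPS total 0.94 Hz; imagery raising IFG→OCC to
more than three times baseline; vividness modulating only IPS→OCC (toward
excitation), FG→OCC (toward inhibition) and the OCC self-connection
(disinhibition); no bottom-up imagery modulation.  All other magnitudes
are approximate transcriptions chosen to respect the published
sign/significance pattern while keeping a −0.40 Hz stability margin at the
group mean.  Perception drives OCC (0.4 Hz); imagery drives IFG (0.3 Hz),
with an optional weak direct OCC drive (0.1 Hz) behind a flag, off by
default so the driving-input ground truth stays identifiable.

Per-trial vividness ratings are i.i.d. categorical with probabilities
(0.0879, 0.2085, 0.3510, 0.3528)/1.0002 (the printed proportions,
normalised; pooled mean 2.97).  Real rating sequences are neither i.i.d.
nor category-independent; the schedule retains category labels so the
centring step is still exercised.  Subject parameters are the group means
plus independent `N(0, 0.1²)` perturbations on every free parameter;
draws violating the stability guard (~9%) are rejected and resampled,
mildly truncating the tails (the sampling-dispersion test bounds the
effect at under 10% of the sd).  Observation noise sd is 1.0 (percent
signal change) against a noiseless signal sd of ~1.3 across regions —
SNR ≈ 1.  The calibration scale is 12 subjects × 40 trials; the full
published design (26 × 180, ~54 min of scanning per subject at the printed
event durations) is available through the same API and is used for the
design-geometry and vividness calibrations, which cost seconds.

**What the generator does not emulate**: voxel-level structure (except via
the explicit rank-1-plus-noise ROI fixture for eigenvariate extraction),
serial correlations, scanner drift, motion, physiological confounds,
category-dependent vividness, behavioural non-stationarity.  Passing
recovery tests therefore demonstrate correctness and calibration of the
inference chain under the model's own assumptions, not robustness to the
full complexity of acquired fMRI.

**Design orthogonality.**  The simulated 180-trial paradigm yields an
absolute cosine of ~0.013 between the HRF-convolved perception and imagery
regressors (resampled at TR = 2 s, uncentred — the design-matrix
convention).  The corresponding in-vivo report for this paradigm is an
order of magnitude larger.  The discrepancy is structural, not a bug: with
back-to-back trials at the printed event durations, the positive overlap
of adjacent responses almost exactly cancels against the undershoot
overlap, and no reading of the statistic (mean-centred: ~0.75; raw
boxcars, centred: ~0.26) reproduces the in-vivo value, which likely
reflects additional modelled events and inter-trial structure (self-paced
ratings, block breaks) absent from the printed timings.  The acceptance
suite keeps the comparison and reports the failure honestly rather than
tuning unreported durations to match.

## Numerical details

- Unstable parameter proposals inside the optimiser are not fatal: their
  predictions are poisoned to infinity, the candidate free energy becomes
  −∞, and the step is rejected.
- `expm` is evaluated batched over (parameter-set × unique-input)
  stacks; the neuronal and haemodynamic recursions are numba-compiled.
- Evidences in model spaces are stored relative to the full model;
  log-sum-exp is used for every family/weight computation.
- Reductions that would make the posterior precision indefinite raise a
  numerical-degeneracy error suggesting a larger clamp variance.
- Empty family convention: if every model of a space excludes a parameter
  its `Pp` is 0; if every model includes it, 1.
- All randomness flows through `numpy` `SeedSequence` spawning from a
  single master seed; inversion and PEB contain no internal randomness,
  and re-running any pipeline with the same configuration is bit-identical.
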