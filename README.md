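# visdcm

Effective-connectivity analysis of a four-region visual network — early
visual cortex (OCC), fusiform gyrus (FG), intraparietal sulcus (IPS) and
inferior frontal gyrus (IFG) — during visual perception and mental imagery,
built as a tested, reusable Python package.  It is aimed at researchers who
want to study (or teach) how directed coupling estimates of the kind used in
task-fMRI connectivity studies behave under known ground truth: every stage
of the analysis can be exercised on synthetic multi-subject data generated
from a documented preset.

## The model

Neuronal dynamics follow the bilinear state equation

```
dz/dt = (A + Σ_j u_j B^j) z + C u
```

where `z` is a vector of regional activities, `A` (Hz) the endogenous
coupling, `B^j` the change in coupling induced by experimental input `u_j`
(here: perception and imagery boxcars and a trial-wise imagery-vividness
modulator), and `C` the direct driving influence of the inputs.  Rows are
targets and columns sources; self-connections are parameterised as
`-0.5·exp(a_self)` Hz so they stay inhibitory.  Activity is mapped to BOLD
through the standard balloon/Windkessel haemodynamic cascade and sampled at
`(k + 0.5)·TR`.

Inference follows the hierarchical Bayesian scheme used in group DCM
studies:

1. **Variational Laplace** per subject: Gauss–Newton ascent on the free
   energy `F = E_q[log p(y|θ)] − KL(q‖prior)`, exact on linear-Gaussian
   models, with a noise log-precision hyperparameter.
2. **Bayesian model reduction (BMR)**: closed-form posteriors and evidences
   of models in which parameters are switched off (prior variance clamped),
   computed from the full model's posterior.
3. **Parametric empirical Bayes (PEB)**: a group-level GLM over subject
   posteriors in which subjects contribute in proportion to their
   first-level precision, with a random-effects precision hyperparameter.
4. **Family inference and BMA**: per-parameter posterior probabilities
   (`Pp`) from evidence-weighted model families, and moment-matched
   Bayesian model averages; effects are reported significant at `Pp ≥ 0.95`.
5. **Pooled contrasts**: bottom-up coupling (connections leaving OCC or
   entering IFG) and top-down coupling (entering OCC or leaving IFG) are
   pooled with equal weights per condition and compared through the exact
   Gaussian of the linear functional.

## Worked example

Simulate a small study from the canonical preset (which encodes the
published coupling pattern: baseline OCC→IPS of 0.05 Hz rising to 0.94 Hz
under perception, imagery more than tripling IFG→OCC, no bottom-up imagery
modulation), invert every subject, pool with PEB/BMA and form the
directional contrasts:

```python
import numpy as np
from visdcm import (paper_ground_truth, generate_study, default_priors, param_names,
                    fit_subjects, modulation_analysis, all_contrasts, InversionOptions)

gt = paper_ground_truth()
study = generate_study(gt, n_subjects=4, n_trials=20, seed=7)
priors = default_priors(param_names(gt.spec))
posteriors = fit_subjects(study, gt.spec, priors,
                          InversionOptions(tol=1e-3, max_iter=96))
result = modulation_analysis(posteriors, np.ones((4, 1)), priors)
mu, sd = result["bma"]["mean:B:perception:IPS<-OCC"]
print(f"perception modulation of OCC->IPS: {mu:.2f} +/- {sd:.2f} Hz")
for name, c in all_contrasts(result["bma"]).items():
    print(f"{name:22s} {c.posterior_mean:+.3f} Hz  Pp(>0) = {c.pp_greater_than_zero:.2f}")
```

Output (about half a minute on one core):

```
perception modulation of OCC->IPS: 0.57 +/- 0.13 Hz
bottom_up_perception   +0.150 Hz  Pp(>0) = 1.00
bottom_up_imagery      -0.053 Hz  Pp(>0) = 0.12
top_down_perception    -0.116 Hz  Pp(>0) = 0.07
top_down_imagery       +0.037 Hz  Pp(>0) = 0.72
```

At this deliberately tiny scale (4 subjects, 20 trials, signal-to-noise
around one) the perception effect on OCC→IPS is already unambiguous —
bottom-up coupling rises strongly under perception (`Pp = 1.00`) — while
the weaker top-down imagery increase is only hinted at (`Pp = 0.72`); at
the calibration scale of 12 subjects × 40 trials it becomes decisive
(`Pp ≥ 0.95`, see below).  The group modulation estimate of 0.57 ± 0.13 Hz
under-resolves the generating 0.89 Hz at n = 4; pooling more subjects moves
it toward the truth.

The same pipeline is scriptable from the shell:

```bash
visdcm pipeline --seed 1 --out results/run1          # simulate + analyse
visdcm simulate --seed 2 --out mystudy               # just write a study
visdcm invert mystudy --out fits                     # per-subject inversion
visdcm contrast results/run1/group_bma_posterior.json --out results/run1
```

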