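# jumppower

Peak external power in the countermovement jump (CMJ) is a standard
monitoring measure for athletes, normally computed from force-platform
recordings that are impractical in the field.  `jumppower` implements a
machine-learning alternative: predict the force-platform criterion from a
single body-worn accelerometer using functional principal component (FPC)
features, with the whole processing + modelling chain tuned by a
surrogate-model-assisted optimiser inside nested cross validation (NCV).

The package is aimed at sports-biomechanics and wearable-sensing
researchers who want to reproduce or extend this modelling chain, and at
anyone needing a low-overhead optimiser for noisy, expensive objectives
over mixed categorical/integer/real parameter spaces.

## What is implemented

* **Criterion computation** — vertical ground reaction force (VGRF,
  1000 Hz) integrated with the trapezoidal rule from jump initiation
  (two-step 8% / 1% body-weight threshold rule); peak power =
  max(v · F)/m in W·kg⁻¹ between initiation and take-off; take-off and
  landing from the 10 N threshold.
* **Functional features** — take-off-aligned windows `[T − t_pre, T + t_post)`
  of the 250 Hz accelerometer signal (resultant or per-axis), smoothed by
  penalised least squares on a b-spline basis of order 4–6 with density
  ρ (functions·s⁻¹) and roughness penalty λ on the 2nd or 3rd derivative;
  unrotated FPCA in the spline basis yields the score predictors.
* **Models** — regularised linear regression (ridge/lasso, least-squares
  or ε-insensitive solver), support vector regression (Gaussian / linear /
  polynomial kernels; box constraint BC, kernel scale KS, tube width ε)
  and Gaussian process regression (four mean bases, five kernels, fixed
  noise σ), with optional z-score standardisation.
* **Objective (AM)** — a full parameter vector maps to the inner 2-fold,
  participant-level cross-validated RMSE, with invalid combinations
  penalised and losses capped at 10 W·kg⁻¹.
* **Optimiser** — constrained random search screened by a Gaussian-process
  surrogate (anisotropic Matérn 5/2), acceptance probability
  `exp(−(L − L_max)²/2δ²)` with a tightening ceiling
  `L_max = L₀ + α_j·SD(L)`, particle swarm optimisation on each refitted
  surrogate, and maximum-likelihood ensemble selection (categorical mode /
  kernel-density peak) over the PSO optima.
* **NCV and analysis** — repeated participant-level K-fold outer loop,
  holdout evaluation with hard leakage guards, iterative refinement
  (freezing peaked parameters), Winsorised Type I factorial ANOVA with
  semi-partial ω² effect sizes and stratified bootstrap intervals.
* **Synthetic cohorts** — a seeded generator of physically consistent CMJ
  trials (quiet standing, unweighting dip, push-off, flight, landing
  spike; impulse balances to zero) with site-specific sensor distortion,
  plus a *linear-link* mode whose target is an exact linear function of
  latent waveform amplitudes — the parameter-recovery surface used by the
  tests.

## Worked example

```python
import numpy as np
from jumppower import (GeneratorConfig, ParamSpace, build_features,
                       generate_dataset, ground_truth_table)
from jumppower.ncv import OptimizerSettings, run_ncv

cfg = GeneratorConfig(n_participants=24, n_holdout=4, seed=7,
                      linear_link=True, link_noise_sd=1.0,
                      noise_sd=0.02, prob_8_jumps=1.0)
cohort, trials = generate_dataset(cfg, "LB")
train = {p.id for p in cohort if p.group == "train"}
feats = build_features([t for t in trials if t.participant_id in train])

space = ParamSpace.for_family("LR")
settings = OptimizerSettings(n_obs=60, refit_every=10, n_particles=30)
result = run_ncv(feats, space, "LR", settings=settings,
                 n_folds=3, n_reps=2, seed=11)
mean, sd = result.ncv_estimate
print(f"NCV RMSE {mean:.2f} +/- {sd:.2f} W/kg")
```

prints

```
NCV RMSE 1.25 +/- 0.36 W/kg
```

on a dataset whose regression target carries 1.0 W·kg⁻¹ of injected
observation noise: the optimised pipeline recovers the latent linear link
to within ~1.3× the noise floor, which is the point of the linear-link
surface.  On a standard (non-linear-link) cohort, `ground_truth_table`
gives criterion peak powers of ≈ 45 W·kg⁻¹ (no arm swing) and
≈ 51 W·kg⁻¹ (arm swing), with flight times of ≈ 480 ms.

A thin CLI mirrors the library:

```bash
jumppower simulate --n-participants 20 --seed 1 --out dataset/
jumppower preprocess dataset/
jumppower ncv --linear-link --n-folds 3 --seed 1 --out ncv.json
```

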