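# Methods

## Criterion peak power

The criterion is computed entirely from the force platform.  Net
acceleration `(F − BW)/m` is integrated with the trapezoidal rule from
jump initiation to give vertical velocity; instantaneous power is
`v · F`, and the criterion is its maximum divided by body mass (W·kg⁻¹).
Initiation uses a two-step rule: find the first sample where
`|F − BW| > 8% BW`, then step back to the first sample of the contiguous
run of `> 1% BW` deviation leading into that crossing.  The deviation is
two-sided because a countermovement starts with unweighting below body
weight.  Take-off is the first sample below 10 N and landing the first
subsequent sample above it; flight time is their difference.  The maximum
power search is restricted to initiation → take-off: power during flight
is not physically meaningful and the landing transient is not part of the
criterion.  Indexing is 0-based with half-open windows; the take-off time
is mapped to the nearest 250 Hz sample when aligning the accelerometer.

Against a rectangular net-force pulse with closed form `2 g² T`, the
1000 Hz trapezoidal integration agrees to ≈ 0.3%.

## Functional representation

Windowed accelerometer curves are smoothed by penalised least squares on
a clamped, uniform-knot b-spline basis.  The basis size is defined by a
density ρ (functions per second), `n_basis = max(order, round(ρ·T))`,
which keeps the basis comparable across window lengths; the floor at the
order keeps the basis valid.  The roughness penalty λ (stored as a log₁₀
exponent spanning 10⁻¹⁰…10¹⁰) acts on the 2nd or 3rd derivative as
selected by the basis code Φ ∈ {4-2, 5-2, 5-3, 6-2, 6-3, 6-4}.

FPCA is carried out in the coefficient space: with Gram matrix `W`
(computed exactly by Gauss–Legendre quadrature per knot interval — the
integrands are piecewise polynomials, so this is not an approximation)
and coefficient covariance `V`, the eigenproblem
`W^{1/2} V W^{1/2} u = μ u` gives eigenfunctions orthonormal under the L²
inner product on the window.  Scores are exact inner products via `W`
rather than grid quadrature; the test suite holds a composite-Simpson
quadrature oracle against them.  No rotation is applied, preserving the
components' independence and their natural decay in amplitude.  Triaxial
data are decomposed per axis and the score blocks concatenated (axis
order x, y, z), since each axis has its own modes of variation.

ρ is treated as a linear-scale real (its plausible optima are single-digit
to low-double-digit densities), while λ, λ_LR, BC, KS, ε and σ are
optimised as log₁₀ exponents.

## Model families

* **LR** — ridge (`sklearn.Ridge`, penalty scaled per observation) or
  lasso, with either a least-squares solver or an ε-insensitive linear
  formulation.  The ε-insensitive l2 case uses `LinearSVR`
  (`C = 1/(n·λ_LR)`); the l1 case uses `SGDRegressor` with
  ε-insensitive loss.  Both ε-insensitive solvers scale their inputs
  internally for numerical stability and invert the scaling at
  prediction — a solver detail independent of the user-facing
  standardisation flag.
* **SVM** — `sklearn.SVR` with Gaussian (`gamma = 1/KS²`), linear or
  polynomial kernel; the polynomial degree is fixed at 3.
* **GPR** — an explicit mean basis (none / constant / linear / pure
  quadratic) fitted by OLS with a Gaussian process on the residuals.
  The noise level σ is fixed (entering as `alpha = σ²`), while kernel
  length scales are refined internally by marginal-likelihood
  maximisation.

With standardisation (Z) on, predictors and outcome are z-scored on the
training set and predictions are always returned in outcome units.

## Objective (AM)

One parameter vector → one loss: the outer training set is split 2-fold
at participant level (floor/ceil halves), FPCA is fitted on each inner
training half alone and used to score both halves, the model is fitted
and validated, and the loss is the capped mean of the two fold RMSEs.
Combinations with too few basis functions for the requested components,
a rank-deficient score matrix, a non-positive or out-of-extent window,
or a singular smoothing system return the cap (10 W·kg⁻¹) without
fitting.  The inner split is redrawn on every call by default — the
stochastic objective the surrogate expects — with a fixed-split option
for deterministic testing.  Participant-disjointness of the halves is
asserted on every call.

## Surrogate-assisted search

Candidates are drawn uniformly over wide ranges that extend beyond the
PSO bounds so the surrogate is well defined at the periphery; integer
and categorical coordinates are rounded before evaluation (bounds padded
0.51/x.49 so rounding is unbiased at the limits).  After every
`refit_every` observations a GP surrogate (anisotropic Matérn 5/2 +
fitted white noise, constant mean offset via target centring, raw
predictors, two optimiser restarts) is refitted to all observations, and
candidates are screened by
`p = 1` if `L̂ ≤ L_max`, else `exp(−(L̂ − L_max)²/(2δ²))`, with
`L_max = L₀ + α_j · SD(L)` and `δ = SD(L)/2`.  Two quantities the source
procedure leaves open are defined as: `L₀` = the minimum surrogate
prediction over the observations to date (making `L_max` a tightening
upper envelope) and `SD(L)` = the standard deviation of surrogate
predictions at the observed points (robust to isolated extreme losses).
Both are config-overridable.  The ramp α_j descends linearly from 0.5 to
0 over the first half of the refits and stays at zero.  If screening
rejects a run of candidates (cap 500) the most probable reject is
force-accepted so progress is guaranteed.

PSO is standard global-best with constriction coefficients (inertia
0.729, cognitive/social 1.494), particles clipped to the padded bounds,
rounding applied inside the swarm's objective, and termination when the
best value improves by less than the tolerance over 20 consecutive
iterations.

The ensemble vector is assembled by maximum likelihood over the PSO
optima from the α = 0 phase: modal category for categoricals (ties to
the lowest index), Gaussian-KDE peak (Silverman bandwidth, 512-point
grid) for numerics, integers rounded afterwards.  Only optima that are
valid parameter combinations are eligible.  Because a density blend of
few optima can occasionally land in a region none of them endorsed, the
assembled ensemble is evaluated once on the training objective and
replaced by the best observed vector if it is clearly worse (worse than
twice the best observed loss plus 0.2 W·kg⁻¹); this uses training data
only.  If the ensemble cannot be fitted at all (singular system), the
fit falls back through the observed vectors in order of loss.

## Nested cross validation

The outer loop is a repeated participant-level K-fold partition (default
2 × 10; each repetition's validation folds partition the cohort).  For
each outer fold the search runs on the outer-train set, the fold
ensemble is trained on outer-train and evaluated on outer-validation,
and the NCV estimate is the mean ± SD of fold RMSEs.  A final ensemble
over all folds' optima is trained on the whole training/validation set
and may be evaluated once on the holdout participants.  Participant
overlap at any boundary (inner, outer, holdout) raises a hard error.
One seeded fold plan is shared across conditions for comparability.

Refinement freezes parameters whose optima distribution is sufficiently
peaked: categoricals when the modal share is ≥ 0.5, numerics when ≥ 50%
of the optima fall within ±5% of the optimisation range around the
density peak.  These explicit, configurable rules replace a judgement
call that has no satisfactory objective formulation; successive rounds
never regrow the free-parameter set.

## Condition statistics

Fold errors over the factorial grid (signal × model × sensor × jump
type) are Winsorised — the n/2 most extreme values at each end of the
range are pulled to the adjacent order statistic, preserving length and
rank order — then fitted by a fixed-effects factorial ANOVA with
sequential (Type I) sums of squares in the order Model, Jump Type,
Sensor, Signal, Model × Jump Type.  Effect size is semi-partial
ω² = (SS_eff − df_eff·MS_err)/(SS_total + MS_err).  Intervals come from
a stratified bootstrap (resampling within condition cells), reported as
the median and 5th/95th percentiles.

## Synthetic data

The generator emulates the cohort the pipeline assumes: body mass
73.1 ± 13.1 kg (truncated > 30 kg), 8 or 16 jumps per participant split
between jump types, flight time 0.48 s with between-participant
(0.055 s) and within-participant (0.036 s) components combining to
≈ 0.066 s overall, and a longer flight with arm swing (+0.045 s) so the
arm-swing condition produces higher peak powers (≈ 51 vs ≈ 45 W·kg⁻¹).

The VGRF waveform is a piecewise parametric template: quiet standing; a
half-cosine unweighting dip (depth ≈ 30% BW); a sinusoidal push-off
pulse whose amplitude is solved so the take-off impulse matches
`m·g·T_f/2`; a 40 ms cosine-squared release to zero force (its sub-10 N
tail is deducted from the flight segment so the detected flight time is
unbiased); ballistic flight; and a gamma-shaped landing spike whose
amplitude is solved so the whole trial's net impulse is zero — the
jumper lands at rest, and event detectors see exact analytic crossings.
The accelerometer is the VGRF in g decimated 1000 → 250 Hz, passed
through a per-site linear distortion (gain, lag, damped landing
resonance) plus white noise and clipped to ±9 g; the two transverse
channels carry attenuated, phase-shifted copies of the dynamic
component, so the resultant is dominated by the vertical channel.

What the generator does *not* emulate: soft-tissue artefact, sensor
orientation drift, inter-trial waveform idiosyncrasies beyond the
parametrised phases, or non-stationary noise.  Passing tests therefore
demonstrate correctness of the pipeline's mechanics and its recovery of
signal structure the generator encodes — not field performance on human
data.

### Linear-link mode

For parameter recovery, latent amplitudes z ~ N(0,1) scale three fixed
Gaussian bumps added to the vertical channel during the push-off phase
(centres −0.30/−0.22/−0.14 s before take-off), where the resultant's
baseline is well above zero so the amplitudes pass linearly into the
magnitude signal; phase-duration nuisance variation is frozen in this
mode so the bumps sit on a stable take-off-aligned baseline.  The target
is exactly `45 + 5z₁ + 3z₂ + 2z₃` plus optional observation noise
(`link_noise_sd`).  With noise sd 1.0 W·kg⁻¹ an optimised FPCA + linear
pipeline reaches a mean outer-fold RMSE of ≈ 1.1–1.3 W·kg⁻¹ — close to
the noise floor, the residual coming from finite samples and the mild
nonlinearity of the resultant.

## Problem sizes and numerical choices

The test suite and reporting script use scaled problem sizes chosen as
the smallest at which each property is stable: 20–24 participants,
2 × 3 outer folds, 60 objective observations per fold with surrogate
refits every 10 and 30 PSO particles; the full-scale study design
(2 × 10 folds, 400 observations, refits every 20, 100 particles) is the
default of `OptimizerSettings` and available throughout.  Basis design
and penalty matrices are memoised per window/basis geometry.  Tolerances:
FPCA eigenvalues agree with a discretised-PCA oracle to ≪ 1%; smoothing
coefficients agree with a direct penalised normal-equations solve to
1e-6 relative.  Degenerate inputs (constant VGRF, no flight, empty
windows, rank-deficient scores, all-equal KDE samples) are handled
explicitly and tested.

## Known limitations

* The human dataset behind the original study is not available; all
  quantitative results here are properties of the synthetic cohorts.
* The ε-insensitive l1 linear solver (SGD) is the least numerically
  robust model option; the search tolerates this through loss capping.
* GP surrogate fitting dominates overhead at large observation counts
  (cubic in observations); the study-scale 400-observation searches are
  tractable but not fast.
* The generator's sensor-site distortions are plausible but not
  calibrated to any specific hardware.
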