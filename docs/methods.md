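# Methods

This note documents the models, parameter choices and numerical decisions
behind `rewardglm`, and what the synthetic benchmarks do and do not
demonstrate about real recordings.

## Task simulator

The simulator emulates an uncertain-target center–out reaching session.

**Trial generation.** The true target angle is drawn from a von Mises prior
centered at 90° (π/2); a cue of 5 line-segment angles is drawn i.i.d. from a
von Mises likelihood centered on the target. Narrow/broad conditions select
the concentration pair; defaults are cue κ = (50, 5) (one animal's values;
(100, 1) reproduces the other) and prior κ = (10, 2) — the prior
concentrations are not constrained by published values and were fixed once as
a plausibly informative/vague pair. The trial's *uncertainty* covariate is
the cue dispersion: the largest pairwise circular distance among the 5
segments.

**Behavior.** The simulated animal aims at the circular mean of the cue
segments — the maximum-likelihood readout, deliberately not a Bayesian
prior–likelihood integration, which is outside this package's scope. The
reach runs 7 cm along a minimum-jerk trajectory whose endpoint angle gets von
Mises motor noise (circular SD 0.06 rad by default). Success requires the
endpoint within the 15°-diameter target window read as ±7.5° of arc at the
ring (a Euclidean-disc criterion would be a one-line change). Reward follows
success except on withheld-reward trials (an explicit boolean flag,
default fraction 0). Movement onset lags the go cue by 35 ms (narrow) or
111 ms (broad) plus N(0, 12 ms) jitter — the configured offsets reproduce the
empirical slowing of reaches under cue uncertainty and are recoverable from
the simulated latencies.

**Event times** (per-trial clock, seconds from trial start): cue at 0.5,
go cue after a uniform 0.8–1.0 s delay, reward onset 0.2 s after the reach
ends, return reach starting 0.5 s after reward onset. Reach durations are
0.4 s ± U(−60, +60) ms, independently for the outward and return movement, so
single-trial speed profiles vary the way real reaches do. Because every
trial carries its own clock, the inter-trial interval has no effect on any
statistic; the configured ITI range is recorded in session metadata only.

**Spike generation** inverts the analysis model exactly: counts per 10-ms
bin over the −0.5..+1.5 s epoch are Poisson with log-rate = baseline +
design-row · ground-truth weights, where the design row comes from the *same*
`build_design_matrix` code path the analysis uses. Parameter recovery is
therefore a genuine inverse problem, not a formatting coincidence. Outside
the epoch, spiking is homogeneous Poisson at the baseline rate. The default
"benchmark" population (20 neurons, 60% PMd) encodes reward with a negative
kernel peaking 400–600 ms after the outcome cue — firing increases after
*unrewarded* outcomes, at the latency regime of the cortical reward signal —
plus moderate velocity/acceleration kernels; amplitudes vary deterministically
across neurons. A "null" population encodes nothing.

**What the simulator does not emulate:** biomechanics/EMG, eye movements,
learning across trials, non-Poisson spiking (refractoriness, bursting),
shared population variability, and electrode artifacts. Passing benchmarks
therefore demonstrates calibration and recoverability of the *statistical
pipeline* under its own generative assumptions, not robustness to every
property of real recordings.

## PSTH analysis

PSTHs use 25-ms bins aligned to reward onset; rates are across-trial means of
count/width with across-trial SEMs. Kinematic matching pairs rewarded with
unrewarded trials greedily by Euclidean distance between speed profiles
resampled to 50 points (movement onset → end of reach, detected as the last
time speed exceeds 5% of its peak); pairs beyond the 0.75 quantile of the
matched-distance distribution are discarded. The matching algorithm is a
design choice — the important part is the explicit post-match balance test
(two-sample t-test on matched mean speeds), which makes "matched" falsifiable
regardless of algorithm.

The reward-modulation test compares per-trial mean rates in [0, 1.5] s after
reward with two one-sided Welch t-tests (one per direction), significant when
the smaller p falls below 0.05/n_neurons (Bonferroni across the population).
Reporting both directions reflects that real populations contain both
up-for-unrewarded and (rarer) up-for-rewarded neurons. Population curves
normalize each neuron's two PSTHs by their *joint* peak — per-condition
normalization would erase the between-condition difference being displayed.

## GLM

- Epoch 200 bins × trials; feature columns = covariate × 4 raised-cosine
  bases; kernels are sampled so the center bin is exactly 1 and the ±200-ms
  boundaries exactly 0, giving each kernel a grid sum of exactly
  width/2 = 0.2 s.
- Lead kernels sit at delays 0, 200, 400, 600 ms (support −200..+800 ms),
  spanning the 400–600 ms reward-signal latency; lag kernels mirror them in
  time for the kinematic channels.
- Convolution pads every trial with 50 zero bins **on both sides** before
  concatenation; padding ≥ kernel half-length makes the result provably
  identical to convolving each trial in isolation (tested against that
  oracle).
- Objective: (1/n)·Poisson deviance + λ(α‖w‖₁ + (1−α)/2‖w‖₂²), λ = 0.1,
  α = 0.1 fixed (no hyperparameter search), intercept unpenalized. Columns
  are centered/scaled inside the solver (glmnet convention) because natural
  feature scales span 1 (impulses) to ~3·10³ (cm/s convolutions); weights are
  reported on the raw scale, and `standardize=False` restores raw-scale
  penalization.
- Solver: IRLS with cyclic coordinate descent on the working quadratic, soft
  thresholding for the L1 term, and a step-halving safeguard that keeps the
  true objective monotonically nonincreasing (the logged objective path is
  asserted monotone in tests). Convergence at relative objective change
  < 1e-9. λ = 0 fits match an independent BFGS Poisson MLE to 1e-5; the
  intercept-only fit uses the closed form log(mean count). Neurons under
  0.5 spikes/s mean epoch rate are excluded with a logged notice.
- Cross-validation splits *trials* (not bins) into two halves, stratified by
  the rewarded flag so neither fold lacks unrewarded trials (a documented
  switch disables stratification).

## Model comparison

Pseudo-R² uses the deviance-normalized McFadden form with the saturated model
as the upper anchor, so values lie in [0, 1] on the training set and may go
negative out of sample. The relative pseudo-R² of covariate *c* compares the
full model against the partial model *refit from scratch* without *c*'s
columns (warm-started from the full fit for speed; the optimum is identical).
Bootstrap CIs (B = 1000, percentile, seeded) resample whole trials on the
test set, preserving within-trial dependence. Fold CIs are pooled as
(min lower, max upper); σ̂ = pooled width / (2·1.96); the effect is 5σ/2σ/none
by whether mean − kσ̂ > 0. A numerical floor (mean ≤ 1e-12 → none) prevents
bit-level residue between numerically identical full and partial fits from
registering as an effect. No multiple-testing correction is applied across
neurons in the battery (an optional switch is deliberately absent from the
default path to keep the battery's counts interpretable as raw counts, which
are expected to include a few false positives).

## Known limitations and calibration results

- **Confound collinearity bounds per-column recovery.** In this task reward
  *is* thresholded reach error, and the return-reach direction cosines are
  geometric functions of the same endpoint that drives the kinematic
  channels. Fisher standard errors evaluated at the true weights give
  per-column SEs of 0.3–0.4 for the error and return-goal kernels at 400
  trials, so the correlation between fitted and true 40-dimensional weight
  vectors plateaus around 0.7–0.8 — an information limit of the study
  conditions, not an optimizer deficiency (the solver matches independent
  optimizers to 1e-5 where identifiable). The covariate battery is immune to
  this: held-out relative pseudo-R² measures predictive contribution, not
  per-column attribution, and calibrates cleanly (benchmark sensitivity
  ≈ 0.99, false-positive rate ≈ 0 on the null confounds).
- **Return-goal false positives on kinematics-coding neurons.** Because the
  L2-heavy penalty spreads genuinely kinematic signal onto the collinear
  return-goal columns, removing them has a real (tiny, ~5·10⁻⁴) held-out
  cost, and the battery flags return_goal on most benchmark neurons even
  though ground truth assigns it no weight. On null populations, where no
  proxy signal exists, its false-positive rate is ≤ 5% like every other
  covariate. Interpret return-goal significance on kinematically driven
  neurons accordingly.
- **PSTH-level prediction R² is noise-limited at desk scale.** The fitted
  model reproduces the *generative* trial-averaged rate with R² ≈ 0.97, but
  the empirical trial-averaged PSTH at 400 trials has per-bin sampling noise
  comparable to the modulation depth, capping predicted-vs-empirical R² near
  0.4 regardless of model quality. Comparisons against empirical PSTHs at
  these trial counts measure mostly PSTH noise.
- Problem sizes used by the benchmarks (400 trials × 20 neurons for the
  battery, 1000 null neurons for PSTH calibration, 40 null neurons × 200
  trials for battery calibration, 1000 trials for behavior) were chosen as
  the smallest populations at which the binomial bounds being checked are
  meaningful.
- Determinism: every random draw descends from one master seed (simulator
  seed + 11, CV split + 23, bootstrap + 37); identical configs produce
  byte-identical `report.json`.
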