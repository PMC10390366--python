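# Methods

`pupilhmm` implements a complete analysis pipeline for a two-block
probabilistic prediction task with concurrent pupillometry: task simulation,
a seven-model space of behavioral models centered on a two-state hidden
Markov belief model, trial-wise uncertainty latents, pupil preprocessing,
and trial-level mixed-effects analyses — together with a synthetic-data
generator that stands in for human data, so every stage is testable end to
end.

## Task environment

Each block has 160 trials (configurable). On every trial one of two stimuli
(left- or right-tilted) appears; within a segment the majority side occurs
with a fixed probability — 80:20 on low-risk and 60:40 on high-risk
segments. Segments last 20 ± 4 trials (uniform on the integers [16, 24]; the
final segment is truncated at the block end), alternate risk level, and flip
the majority side at every change point. The *cued* block reuses the
volatile block's change trials exactly, inverts the majority side
(`p_left -> 1 - p_left`), and announces each change; the *volatile* block
hides them. Trial indices are 1-based and segment intervals closed, so a
change "on trial 21" means trial 21 already belongs to the new segment.
Warm-up/training trials are not modeled; all analyses operate on the main
trials only.

## Behavioral models

All models output a per-trial probability of predicting "left", turned into
choices by a logistic rule with one inverse temperature:
`P(left) = logistic(inv_temp * (2 b - 1))` for belief models (`b` the
probability of the "predominantly left" state) and
`logistic(inv_temp * (V_L - V_R))` for value models. No lapse parameter is
included. Beliefs and values start uniform (0.5).

* **wsls** — probabilistic win-stay-lose-shift: repeat with `p_stay_win`
  after a correct prediction, switch with `p_shift_lose` after an error.
* **rescorla_wagner** — single learning rate toward reward `r = 1` for a
  correct prediction, 0 otherwise (the task has no monetary outcomes).
* **dual_rate** — separate learning rates after rewarded vs unrewarded
  trials.
* **pearce_hall** — learning rate gated by an evolving associability
  `kappa <- (1 - eta) kappa + eta |delta|`, initialized at `kappa0`.
* **double_update** — chosen value moves toward `r`, unchosen toward
  `1 - r`.
* **hmm** / **hmm_rp** — two-state hidden Markov filter. The transition
  probability `gamma` (the probability the hidden task state switches per
  trial) is the model's operationalization of subjective volatility. Each
  trial alternates a transition step
  `b_pre = (1 - gamma) b_post' + gamma (1 - b_post')` with a Bayes update by
  the observed stimulus, whose emission strength is constrained to
  (0.5, 1). In `hmm_rp` the emission strength differs after correct
  (`c_pos`) versus incorrect (`c_neg`) predictions; `hmm` ties them. For
  cued blocks the filter supports belief resets: at announced change trials
  the pre-outcome belief is set back to uniform, replacing the transition
  step. Resets go to exactly 0.5 (a learned prior would be an alternative;
  uniform is the simplest defensible choice and matches the instruction to
  "start anew").

The recursive filter is verified in the test suite against brute-force
enumeration over all `2^T` hidden-state paths at tolerance 1e-10.

## Latent learning signals

From the HMM_RP belief trajectory two trial-wise signals are derived, both
in nats (natural log; the base only rescales and is removed by z-scoring):

* **Bayesian surprise** `KL(post || pre)` — the divergence of the
  post-outcome from the pre-outcome state belief; the warranted
  belief-update magnitude. The divergence is computed with post-outcome
  weighting, the standard orientation for which the quantity is
  non-negative; an orientation that weights the log-ratio by the
  pre-outcome belief would equal `-KL(pre || post)` and could not serve as
  a surprise signal.
* **Choice uncertainty** — the Shannon entropy of the state belief. It is
  evaluated on the *pre-outcome* belief by default (the uncertainty under
  which the choice was made); a switch (`entropy_on="post"`) selects the
  post-outcome belief instead, since either convention is defensible.

For the pupil analyses both signals are z-scored within participant x
block. The cube-root transform (for surprise) and signed square root (for
maximum dilation) are provided as variance-stabilizing transforms.

## Fitting

**Per-session point fits** optimize on unconstrained scales (logit for
probabilities, a scaled logit mapping onto (0.5, 1) for emission strengths,
log for the inverse temperature; the log scale is clipped to [-8, 6] to
keep the objective finite) with L-BFGS from `n_starts` seeded jittered
initializations. By default the objective includes a weakly informative
Gaussian ridge `N(0, 1.5)` on the unconstrained parameters (a MAP
estimate). This is not cosmetic: a single session leaves a scaling ridge
between the emission strength and the inverse temperature nearly
unidentified (`c -> 0.5` with `inv_temp -> infinity` reproduces the same
choice probabilities), and unregularized ML reliably drifts to such
degenerate corners. In the package's recovery battery (50 observers, 320
trials, `gamma` in [0.02, 0.40]) the regularized fit recovers `gamma` at
Spearman rho ≈ 0.82 where pure ML achieves ≈ 0.38. `prior_sd=None`
restores pure ML; reported log likelihoods and AIC/BIC always use the data
likelihood only, with `n = n_trials` in BIC and a per-trial likelihood
floor of 1e-12 guarding deterministic corners.

**Hierarchical fits** place Gaussian population distributions over the
transformed per-subject parameters (non-centered parameterization;
hyperpriors `mu ~ N(0, 2)`, `sigma ~ HalfNormal(1)`) and sample the joint
posterior with affine-invariant ensemble MCMC. Convergence is summarized by
split R-hat per group-level parameter, treating walkers as chains, with the
fit flagged (never silently returned) when any R-hat exceeds 1.01.
Posterior draws of `gamma` are retained on the natural scale so the two
blocks can be contrasted by the mean difference and highest-density
interval of paired draws. Volatile and cued blocks are always fitted
independently (separate parameter sets).

**Model comparison** ranks models by summed BIC (AIC selectable) over a
cohort with identical participant x block coverage; ties break
alphabetically by model id, and per-participant best-fit counts are
reported alongside.

## Pupil preprocessing

The chain assumes a uniform 500 Hz sample grid and runs, in order:

1. **Artifact detection** — samples whose absolute velocity (first
   difference) exceeds `median + k * MAD` of the per-trace velocity
   distribution are flagged (default `k = 6`; thresholds are per trace,
   standing in for per-individual manual adaptation), as are zero or
   non-finite diameters. Two refinements matter in practice: an isolated
   super-threshold velocity sample is almost always a noise excursion, so a
   fast *neighbor* is required before flagging (artifact transitions are
   sustained); and the threshold has an absolute floor
   (`min_velocity = 0.05` units/sample) because on near-noiseless signals
   the MAD collapses to the scale of the slow event-evoked response. Blink
   velocities are orders of magnitude above both. Flagged runs are expanded
   by margins (60 ms before, 120 ms after, configurable per trace).
2. **Interpolation** — each flagged gap is bridged by a cubic spline
   through four denoised control points (two per side, each the mean of a
   50 ms window of clean samples). Anchoring the spline on raw noisy
   samples instead makes the bridging cubic overshoot by several signal
   units inside long gaps. Gaps longer than 1,000 ms, and boundary gaps
   with no flank, are set to missing rather than interpolated.
3. **Smoothing** — third-order low-pass Butterworth at 3 Hz, applied
   forward-backward (zero phase, so event-locked peaks are not delayed)
   within each contiguous non-missing segment.
4. **Normalization** — z-scoring per block and participant over non-missing
   samples; interpolated samples are included in the statistics, only
   missing spans are excluded.
5. **Epoching** — per trial, baseline = mean over `[onset - 500, onset)`
   ms; corrected epoch = z-signal minus baseline over `[onset, onset +
   2000)` ms (half-open windows, integer-ms grid). A trial is valid only if
   both windows contain at most 50% interpolated-or-missing samples;
   statistics over a window ignore missing samples but count them toward
   the corrupted fraction. The readout is the maximum of the corrected
   epoch, with a signed square root (`sign(x) sqrt(|x|)`) since
   baseline-corrected maxima can be negative.

## Statistical models

Behavioral summaries per participant x block x risk: accuracy (frequency of
predicting the current majority stimulus) and switch rate (frequency of
changing prediction between consecutive trials; a switch belongs to the
risk condition of the destination trial, and block boundaries contribute no
transition).

All mixed models are fitted by REML with z-scored continuous variables and
effect-coded (-0.5/+0.5) two-level factors, so coefficients are
standardized; Wald tests are two-sided with the engine's large-sample
normal reference. Nested random intercepts are expressed as variance
components grouped by participant. In the 4-cells-per-participant summary
model the deepest component (risk within block) has one observation per
level and is confounded with the residual; it is retained for fidelity to
the nested specification and may estimate at the boundary.

The trial-level pupil models regress the square-root-transformed maximum
dilation of QC-passing trials on a z-scored latent, block, a trait score,
and all interactions, separately per latent (entropy, surprise) and per
trait (AQ, CAPE-P). In addition to intercepts for participant and block
within participant, the default includes per-participant random slopes for
the latent and its block interaction. Calibration measured on null
synthetic studies motivates this: with intercept-only random effects the
trait-moderated slope terms are tested against a standard error that
ignores between-subject slope variability (pupil readouts are temporally
autocorrelated), giving a ~13% false-positive rate at nominal 5%; with the
random slopes the measured rate is 5%, with no loss of power on strong
planted effects. `random_slopes=False` restores the intercept-only
structure.

Trait-volatility associations use Spearman rank correlations (two-sided),
requiring at least five complete pairs.

## Synthetic-data generator

`StudyConfig` defaults encode the emulated study: 52 subjects, two
160-trial blocks, AQ ~ mean 0.30 / SD 0.15 on [0, 1] and CAPE-P ~ mean
1.46 / SD 0.30 on [1, 4] (truncated normals whose *truncated* means equal
the configured values; the location is solved numerically), group-mean
transition probabilities 0.22 (volatile) and 0.10 (cued) on the logit
scale with SD 0.5, emission strengths around 0.80/0.72, and log-normal
inverse temperatures around 5. A Gaussian copula links a configurable
trait to the per-block `gamma` at configured rank correlations (defaults
0.16 volatile / 0.28 cued against CAPE-P), converting rank to Pearson
correlation via `r = 2 sin(pi rho / 6)` so marginals and rank correlations
stay independently controllable. AQ and CAPE-P correlate at rank 0.25.

Pupil traces are generated at 500 Hz as: baseline (5 a.u.) + slow
sinusoidal drift (amplitude 0.1, 2-minute period, random phase) + one
event response per trial, time-locked to outcome onset, using a
gamma-family impulse response peaking ~930 ms post-onset (the standard
pupillometric response kernel; the response shape is configuration, not an
empirical claim), + Gaussian sample noise (SD 0.05) + Poisson blink
artifacts (default 10/min; linear collapse to zero over 8 ms, 100–200 ms
at floor, 40 ms recovery — detectable by a velocity filter by
construction). The response amplitude on trial t is
`a0 + s_E z_entropy_t + s_S z_surprise_t`, where the gains carry planted
block- and trait-moderation terms — exactly the three-way structure the
trial-level pupil models are designed to detect. Trials span 4,000 ms with
the outcome onset at 1,500 ms; the behavioral response period is abstracted
away. Planted effect sizes are free parameters for power experiments, not
estimates of any empirical effect. Ground truth (true parameters and
planted gains) is always written beside generated data.

What the generator does *not* emulate: gaze-dependent foreshortening,
pupil light reflexes, saccade-related transients, non-stationary blink
rates, or drifting (rather than piecewise-constant) outcome
probabilities. Passing tests therefore demonstrate the pipeline's internal
consistency and statistical calibration under the stated generative
assumptions, not robustness to every artifact of real recordings.

## Validation batteries and problem sizes

`pupilhmm.validate` holds the standing evaluation suites, used by the test
suite and by `scripts/acceptance.py`: 1,000-schedule structural checks;
parameter recovery (50 observers x 320 trials); model recovery (cohorts of
20 agents at 160 trials per generating family: WSLS, single-rate RL,
HMM_RP, compared by summed BIC); a 100-session latent-direction battery
using the study's block-specific volatilities; a 100-trace blink-detection
benchmark with ground-truth masks plus a 100-trial amplitude-recovery
fixture; and end-to-end planted-effect recovery (strong studies at N = 52
with 40 trials per block; null studies at N = 24 with 30 trials per
block). Reduced trial counts for the end-to-end batteries are the
package's chosen problem sizes; effect strength for the "strong" battery
is `surprise_block_trait_gain = 0.30` with modest main-effect gains.

## Known limitations

* The exact parameterizations of the paper-adjacent literature's RL
  variants and response models vary; the canonical forms implemented here
  are documented above and fixed by tests, but no claim is made that they
  match any specific prior implementation detail-for-detail.
* The hierarchical sampler is an ensemble method run in a modest number of
  steps; for publication-grade posteriors one would run longer chains (the
  convergence flag and R-hat values make this visible).
* Mixed-model p-values use the large-sample normal reference rather than a
  denominator-degrees-of-freedom correction; with ~50 participants the
  difference is small, and the calibration battery bounds its practical
  effect.
* The pupil QC rule is binary (valid/invalid at 50% corruption); no partial
  weighting is attempted.
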