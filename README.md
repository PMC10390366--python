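# pupilhmm

Hidden-Markov belief modelling and pupillometry analysis for two-block
probabilistic prediction (reversal-learning) tasks.

In these tasks a participant predicts, trial by trial, which of two stimuli
will appear next. The generative probability of the majority stimulus is
fixed within a segment (80:20 under low risk, 60:40 under high risk) and
reverses every ~20 trials — silently in a *volatile* block, with an
on-screen announcement in a *cued* block. The scientific questions the
package serves: how do people represent volatility and risk; how do
trial-wise learning signals derived from a belief model relate to pupil
dilation (a proxy for locus-coeruleus/norepinephrine activity); and how are
those relationships moderated by autistic-like traits (AQ) and
psychotic-like experiences (CAPE-P)?

## The model at the core

Behavior is modeled by a space of seven agents — probabilistic
win-stay-lose-shift, four reinforcement-learning variants, and two
two-state hidden Markov models. The centerpiece, `hmm_rp`, filters a belief
*b* = P(state "predominantly left") through alternating steps

    b_pre(t)  = (1 - γ) b_post(t-1) + γ (1 - b_post(t-1))         (transition)
    b_post(t) ∝ b_pre(t) · c   or   b_pre(t) · (1 - c)            (Bayes update)

with transition probability γ (subjective volatility), emission strength
c = c_pos after a correct and c = c_neg after an incorrect prediction, and
belief resets to uniform at announced change points in the cued block.
Choices follow `P(left) = logistic(β (2 b_pre - 1))`.

Two trial-wise latents are derived from the belief trajectory (in nats):

* Bayesian surprise `D_KL(P(S_post) ‖ P(S_pre)) = Σ_i P_post(i) ln(P_post(i)/P_pre(i))`
* choice uncertainty `H(S) = −Σ_i P(S=i) ln P(S=i)`

Pupil traces (500 Hz) pass a preprocessing chain — velocity-based blink
detection, cubic-spline interpolation (gaps > 1,000 ms become missing),
zero-phase 3 Hz Butterworth smoothing, per-block z-scoring, and per-trial
baseline correction (500 ms pre-outcome) over a 2,000 ms outcome window —
yielding a per-trial maximum dilation. Linear mixed-effects models then
relate accuracy, switching, the latents, and pupil dilation to block, risk,
and trait scores. A synthetic-study generator (traits, model parameters,
behavior, and raw pupil traces with planted trait-moderated coupling)
stands in for human data and makes every stage testable.

## Worked example

```python
import numpy as np
from pupilhmm import (
    HMMRPParams, generate_schedule, derive_cued_schedule, sample_outcomes,
    simulate_agent, filter_beliefs, fit_mle, bayesian_surprise, choice_entropy,
)

vol = generate_schedule(n_trials=160, base_length=20, jitter=4, seed=1)
out = sample_outcomes(vol, seed=2)
true = HMMRPParams(gamma=0.22, c_pos=0.80, c_neg=0.72, inv_temp=5.0)
session = simulate_agent("hmm_rp", true, vol, out, seed=3)

fit = fit_mle("hmm_rp", session, n_starts=10, seed=0)
print({k: round(v, 3) for k, v in fit.params.items()}, round(fit.bic, 1))

traj = filter_beliefs(session, true)
print(round(float(np.mean(bayesian_surprise(traj.b_pre, traj.b_post))), 4),
      round(float(np.mean(choice_entropy(traj.b_pre))), 4))
```

prints

```
{'gamma': 0.124, 'c_pos': 0.832, 'c_neg': 0.819, 'inv_temp': 3.986} 139.8
0.1215 0.6298
```

— a weak-MAP fit from a single 160-trial block: the transition probability
(here 0.124 against a generating 0.22) is recovered only roughly from one
block, which is exactly why volatility inferences should pool over a
cohort (see the recovery battery: rank correlation ≈ 0.8 over 50
observers at 320 trials). The second line is the session's mean Bayesian
surprise and mean choice uncertainty in nats.

A command-line interface mirrors the library
(`pupilhmm simulate-task / generate-study / fit / compare /
pupil-preprocess / analyze`); see `pupilhmm --help`.

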