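"""Behavioral model space for the probabilistic prediction task.

Seven candidate models generate trial-wise choice probabilities from the
history of predictions and observed stimuli:

* ``wsls`` — probabilistic win-stay-lose-shift;
* four reinforcement-learning variants (``rescorla_wagner``, ``dual_rate``,
  ``pearce_hall``, ``double_update``) tracking stimulus values;
* two hidden Markov models over the latent task state
  ("predominantly left" vs "predominantly right"): ``hmm`` with a single
  emission strength and ``hmm_rp``, in which belief updates after correct
  (positive) and incorrect (negative) predictions are allowed to differ.

The HMM transition probability ``gamma`` is the per-trial probability that
the hidden state switches and operationalizes subjective volatility. For the
cued block, beliefs can be reset to the uniform prior at announced change
points. Choices follow a logistic rule on the belief (or value) difference
with one inverse-temperature parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .task import OutcomeSequence, RiskSchedule

__all__ = [
    "HMMRPParams",
    "RLParams",
    "WSLSParams",
    "BeliefTrajectory",
    "BehaviorSession",
    "MODEL_NAMES",
    "MODEL_PARAM_NAMES",
    "hmm_predict_step",
    "hmm_update_step",
    "choice_probability",
    "filter_beliefs",
    "rl_step",
    "wsls_probability",
    "simulate_agent",
]

MODEL_NAMES = (
    "wsls",
    "rescorla_wagner",
    "dual_rate",
    "pearce_hall",
    "double_update",
    "hmm",
    "hmm_rp",
)

# parameter order used throughout fitting; transforms: u = logit on (0,1),
# h = scaled logit on (0.5,1), p = log on (0, inf)
MODEL_PARAM_NAMES: dict[str, tuple[tuple[str, str], ...]] = {
    "wsls": (("p_stay_win", "u"), ("p_shift_lose", "u")),
    "rescorla_wagner": (("alpha", "u"), ("inv_temp", "p")),
    "dual_rate": (("alpha_pos", "u"), ("alpha_neg", "u"), ("inv_temp", "p")),
    "pearce_hall": (("kappa0", "u"), ("eta", "u"), ("inv_temp", "p")),
    "double_update": (("alpha", "u"), ("inv_temp", "p")),
    "hmm": (("gamma", "u"), ("c", "h"), ("inv_temp", "p")),
    "hmm_rp": (("gamma", "u"), ("c_pos", "h"), ("c_neg", "h"), ("inv_temp", "p")),
}


def _check_open(name: str, value: float, lo: float, hi: float) -> None:
    if not lo < value < hi:
        raise ValueError(f"{name}={value} outside open interval ({lo}, {hi})")


@dataclass(frozen=True)
class HMMRPParams:
    """Hidden-Markov belief model parameters.

    gamma
        Transition probability of the hidden task state per trial
        (subjective volatility), in (0, 1).
    c_pos, c_neg
        Emission strengths applied after a correct / incorrect prediction,
        each in (0.5, 1): the believed probability that the majority-state
        stimulus is shown. Tie c_pos == c_neg for the single-c model.
    inv_temp
        Inverse temperature of the logistic choice rule, > 0.
    """

    gamma: float
    c_pos: float
    c_neg: float
    inv_temp: float

    def __post_init__(self) -> None:
        _check_open("gamma", self.gamma, 0.0, 1.0)
        _check_open("c_pos", self.c_pos, 0.5, 1.0)
        _check_open("c_neg", self.c_neg, 0.5, 1.0)
        if self.inv_temp <= 0:
            raise ValueError("inv_temp must be positive")


@dataclass(frozen=True)
class RLParams:
    """Reinforcement-learning model parameters (variant-specific rates)."""

    variant: str
    inv_temp: float
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    kappa0: float | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        if self.inv_temp <= 0:
            raise ValueError("inv_temp must be positive")
        needed = {
            "rescorla_wagner": ("alpha",),
            "dual_rate": ("alpha_pos", "alpha_neg"),
            "pearce_hall": ("kappa0", "eta"),
            "double_update": ("alpha",),
        }
        if self.variant not in needed:
            raise KeyError(f"unknown RL variant {self.variant!r}")
        for name in needed[self.variant]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.variant} requires {name}")
            _check_open(name, value, 0.0, 1.0)


@dataclass(frozen=True)
class WSLSParams:
    """Probabilistic win-stay-lose-shift parameters, both in [0, 1]."""

    p_stay_win: float
    p_shift_lose: float

    def __post_init__(self) -> None:
        for name in ("p_stay_win", "p_shift_lose"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class BeliefTrajectory:
    """Per-trial state beliefs P(state = 'predominantly left').

    ``b_pre`` is the belief before observing the trial's outcome (the belief
    under which the choice is made); ``b_post`` after the Bayes update.
    """

    b_pre: np.ndarray
    b_post: np.ndarray
    reset_applied: np.ndarray


@dataclass
class BehaviorSession:
    """One participant x block sequence of choices and outcomes."""

    participant: str
    block_label: str
    choices: np.ndarray  # str array, "left"/"right"
    outcomes: np.ndarray
    correct: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=object)
        self.outcomes = np.asarray(self.outcomes, dtype=object)
        recomputed = self.choices == self.outcomes
        if self.correct is None:
            self.correct = recomputed
        elif not np.array_equal(np.asarray(self.correct, bool), recomputed):
            raise ValueError("correct flags inconsistent with choices/outcomes")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    def choices_left(self) -> np.ndarray:
        return (self.choices == "left").astype(np.int8)

    def outcomes_left(self) -> np.ndarray:
        return (self.outcomes == "left").astype(np.int8)


# ---------------------------------------------------------------------------
# elementary steps


def hmm_predict_step(b_post_prev: float, gamma: float) -> float:
    """Propagate a state belief one trial through the transition model."""
    return (1.0 - gamma) * b_post_prev + gamma * (1.0 - b_post_prev)


def hmm_update_step(b_pre: float, outcome: str, prev_correct: bool, params: HMMRPParams) -> float:
    """Bayes-update a state belief with the observed stimulus.

    The emission strength is ``c_pos`` if the trial's prediction was correct
    and ``c_neg`` otherwise; the observed stimulus has likelihood ``c`` under
    the congruent state and ``1 - c`` under the incongruent one.
    """
    c = params.c_pos if prev_correct else params.c_neg
    if outcome == "left":
        num = b_pre * c
        den = num + (1.0 - b_pre) * (1.0 - c)
    else:
        num = b_pre * (1.0 - c)
        den = num + (1.0 - b_pre) * c
    return num / den


def choice_probability(b_pre: float, inv_temp: float) -> float:
    """Probability of predicting 'left': logistic(inv_temp * (2 b - 1))."""
    if inv_temp <= 0:
        raise ValueError("inv_temp must be positive")
    x = inv_temp * (2.0 * np.asarray(b_pre, dtype=float) - 1.0)
    # expit written out to keep scalar inputs scalar
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.isscalar(b_pre) or np.ndim(b_pre) == 0 else out


def rl_step(values, choice: str, reward: int, params: RLParams, associability: float | None = None):
    """One value update. Returns new (V_left, V_right) and, for the
    Pearce-Hall variant, the updated associability."""
    v_left, v_right = float(values[0]), float(values[1])
    chose_left = choice == "left"
    v_c = v_left if chose_left else v_right
    delta = reward - v_c
    if params.variant == "rescorla_wagner":
        v_c += params.alpha * delta
    elif params.variant == "dual_rate":
        rate = params.alpha_pos if reward == 1 else params.alpha_neg
        v_c += rate * delta
    elif params.variant == "pearce_hall":
        if associability is None:
            associability = params.kappa0
        v_c += associability * delta
        associability = (1.0 - params.eta) * associability + params.eta * abs(delta)
    elif params.variant == "double_update":
        v_c += params.alpha * delta
        v_u = v_right if chose_left else v_left
        v_u += params.alpha * ((1 - reward) - v_u)
        if chose_left:
            v_right = v_u
        else:
            v_left = v_u
    if chose_left:
        v_left = v_c
    else:
        v_right = v_c
    if params.variant == "pearce_hall":
        return (v_left, v_right), associability
    return (v_left, v_right)


def wsls_probability(prev_choice: str, prev_correct: bool, params: WSLSParams) -> float:
    """Probability of repeating the previous choice."""
    return params.p_stay_win if prev_correct else 1.0 - params.p_shift_lose


# ---------------------------------------------------------------------------
# sequence-level kernels (numba)


@njit(cache=True)
def _hmm_filter_core(outcomes_left, correct, resets, gamma, c_pos, c_neg):
    n = outcomes_left.shape[0]
    b_pre = np.empty(n)
    b_post = np.empty(n)
    b = 0.5
    for t in range(n):
        if t == 0 or resets[t]:
            bp = 0.5
        else:
            bp = (1.0 - gamma) * b + gamma * (1.0 - b)
        b_pre[t] = bp
        c = c_pos if correct[t] else c_neg
        if outcomes_left[t]:
            num = bp * c
            den = num + (1.0 - bp) * (1.0 - c)
        else:
            num = bp * (1.0 - c)
            den = num + (1.0 - bp) * c
        b = num / den
        b_post[t] = b
    return b_pre, b_post


@njit(cache=True)
def _loglik_from_p_left(p_left, choices_left, floor):
    ll = 0.0
    for t in range(p_left.shape[0]):
        p = p_left[t] if choices_left[t] else 1.0 - p_left[t]
        if p < floor:
            p = floor
        ll += np.log(p)
    return ll


@njit(cache=True)
def _hmm_loglik_core(choices_left, outcomes_left, resets, gamma, c_pos, c_neg, inv_temp, floor):
    n = choices_left.shape[0]
    ll = 0.0
    b = 0.5
    for t in range(n):
        if t == 0 or resets[t]:
            bp = 0.5
        else:
            bp = (1.0 - gamma) * b + gamma * (1.0 - b)
        pl = 1.0 / (1.0 + np.exp(-inv_temp * (2.0 * bp - 1.0)))
        p = pl if choices_left[t] else 1.0 - pl
        if p < floor:
            p = floor
        ll += np.log(p)
        corr = choices_left[t] == outcomes_left[t]
        c = c_pos if corr else c_neg
        if outcomes_left[t]:
            num = bp * c
            den = num + (1.0 - bp) * (1.0 - c)
        else:
            num = bp * (1.0 - c)
            den = num + (1.0 - bp) * c
        b = num / den
    return ll


@njit(cache=True)
def _rl_loglik_core(choices_left, outcomes_left, variant, p1, p2, inv_temp, floor):
    # variant: 0 = rescorla_wagner, 1 = dual_rate, 2 = pearce_hall, 3 = double_update
    n = choices_left.shape[0]
    ll = 0.0
    vl = 0.5
    vr = 0.5
    kappa = p1  # pearce_hall: p1 = kappa0, p2 = eta
    for t in range(n):
        pl = 1.0 / (1.0 + np.exp(-inv_temp * (vl - vr)))
        p = pl if choices_left[t] else 1.0 - pl
        if p < floor:
            p = floor
        ll += np.log(p)
        r = 1.0 if choices_left[t] == outcomes_left[t] else 0.0
        if choices_left[t]:
            vc = vl
        else:
            vc = vr
        delta = r - vc
        if variant == 0:
            vc += p1 * delta
        elif variant == 1:
            rate = p1 if r == 1.0 else p2
            vc += rate * delta
        elif variant == 2:
            vc += kappa * delta
            kappa = (1.0 - p2) * kappa + p2 * abs(delta)
        else:
            vc += p1 * delta
            if choices_left[t]:
                vr += p1 * ((1.0 - r) - vr)
            else:
                vl += p1 * ((1.0 - r) - vl)
        if choices_left[t]:
            vl = vc
        else:
            vr = vc
    return ll


@njit(cache=True)
def _wsls_loglik_core(choices_left, outcomes_left, p_stay_win, p_shift_lose, floor):
    n = choices_left.shape[0]
    ll = np.log(0.5)
    for t in range(1, n):
        prev_correct = choices_left[t - 1] == outcomes_left[t - 1]
        p_rep = p_stay_win if prev_correct else 1.0 - p_shift_lose
        p = p_rep if choices_left[t] == choices_left[t - 1] else 1.0 - p_rep
        if p < floor:
            p = floor
        ll += np.log(p)
    return ll


def _resets_array(n: int, reset_trials) -> np.ndarray:
    resets = np.zeros(n, dtype=np.bool_)
    for t in reset_trials or ():
        if not 1 <= t <= n:
            raise IndexError(f"reset trial {t} outside 1..{n}")
        resets[t - 1] = True
    return resets


def filter_beliefs(
    session: BehaviorSession,
    params: HMMRPParams,
    reset_trials=None,
) -> BeliefTrajectory:
    """Run the alternating predict/update recursion over a session.

    At each reset trial (cued change announcements) the pre-outcome belief is
    set back to the uniform prior, replacing the transition step.
    """
    resets = _resets_array(session.n_trials, reset_trials)
    b_pre, b_post = _hmm_filter_core(
        session.outcomes_left(),
        session.correct.astype(np.int8),
        resets,
        params.gamma,
        params.c_pos,
        params.c_neg,
    )
    return BeliefTrajectory(b_pre=b_pre, b_post=b_post, reset_applied=resets)


# ---------------------------------------------------------------------------
# agent simulation


def _simulate_hmm(params: HMMRPParams, outcomes_left, resets, rng) -> np.ndarray:
    n = len(outcomes_left)
    choices_left = np.zeros(n, dtype=np.int8)
    b = 0.5
    for t in range(n):
        bp = 0.5 if (t == 0 or resets[t]) else hmm_predict_step(b, params.gamma)
        pl = 1.0 / (1.0 + np.exp(-params.inv_temp * (2.0 * bp - 1.0)))
        choices_left[t] = rng.random() < pl
        corr = choices_left[t] == outcomes_left[t]
        c = params.c_pos if corr else params.c_neg
        if outcomes_left[t]:
            b = bp * c / (bp * c + (1 - bp) * (1 - c))
        else:
            b = bp * (1 - c) / (bp * (1 - c) + (1 - bp) * c)
    return choices_left


def _simulate_rl(params: RLParams, outcomes_left, rng) -> np.ndarray:
    n = len(outcomes_left)
    choices_left = np.zeros(n, dtype=np.int8)
    values = (0.5, 0.5)
    kappa = params.kappa0 if params.variant == "pearce_hall" else None
    for t in range(n):
        pl = 1.0 / (1.0 + np.exp(-params.inv_temp * (values[0] - values[1])))
        choices_left[t] = rng.random() < pl
        choice = "left" if choices_left[t] else "right"
        r = int(choices_left[t] == outcomes_left[t])
        if params.variant == "pearce_hall":
            values, kappa = rl_step(values, choice, r, params, kappa)
        else:
            values = rl_step(values, choice, r, params)
    return choices_left


def _simulate_wsls(params: WSLSParams, outcomes_left, rng) -> np.ndarray:
    n = len(outcomes_left)
    choices_left = np.zeros(n, dtype=np.int8)
    for t in range(n):
        if t == 0:
            p_left = 0.5
        else:
            prev_correct = bool(choices_left[t - 1] == outcomes_left[t - 1])
            p_rep = wsls_probability("left", prev_correct, params)
            p_left = p_rep if choices_left[t - 1] else 1.0 - p_rep
        choices_left[t] = rng.random() < p_left
    return choices_left


def simulate_agent(
    model: str,
    params,
    schedule: RiskSchedule,
    outcomes: OutcomeSequence,
    seed: int = 0,
    reset_trials=None,
    participant: str = "sim",
) -> BehaviorSession:
    """Simulate an agent of ``model`` against a fixed outcome sequence.

    Choices are sampled from the model's trial-wise choice probabilities;
    the hidden belief/value dynamics are driven by the agent's own sampled
    choices and the given outcomes. Reproducible under ``seed``.
    """
    if model not in MODEL_NAMES:
        raise KeyError(f"unknown model {model!r}")
    if len(outcomes) != schedule.n_trials:
        raise ValueError("outcomes length does not match schedule")
    rng = np.random.default_rng(seed)
    outcomes_left = np.array([s == "left" for s in outcomes.stimuli], dtype=np.int8)
    resets = _resets_array(schedule.n_trials, reset_trials)
    if model in ("hmm", "hmm_rp"):
        choices_left = _simulate_hmm(params, outcomes_left, resets, rng)
    elif model == "wsls":
        choices_left = _simulate_wsls(params, outcomes_left, rng)
    else:
        choices_left = _simulate_rl(params, outcomes_left, rng)
    choices = np.where(choices_left, "left", "right").astype(object)
    outcome_arr = np.where(outcomes_left, "left", "right").astype(object)
    return BehaviorSession(
        participant=participant,
        block_label=schedule.block_label,
        choices=choices,
        outcomes=outcome_arr,
    )
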