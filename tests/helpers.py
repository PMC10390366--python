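"""Independent brute-force oracles used by the test suite.

The path-enumeration oracle computes hidden-state beliefs by summing over
all 2^T state paths; it shares no code with the recursive filter it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_beliefs(outcomes_left, correct, gamma, c_pos, c_neg, resets=None):
    """Exact pre-/post-outcome beliefs P(state = left) by summing over every
    hidden-state path.

    State ``1`` ("predominantly left") emits a left stimulus with
    probability ``c_t`` (``c_pos`` when the trial's prediction was correct,
    ``c_neg`` otherwise); the chain starts uniform and transitions with
    probability ``gamma``, except at reset trials where the state prior is
    uniform again.
    """
    outcomes_left = np.asarray(outcomes_left, dtype=int)
    correct = np.asarray(correct, dtype=bool)
    T = len(outcomes_left)
    if resets is None:
        resets = np.zeros(T, dtype=bool)
    resets = np.asarray(resets, dtype=bool)
    c = np.where(correct, c_pos, c_neg)

    paths = np.array(list(itertools.product((0, 1), repeat=T)))  # (2^T, T)
    # prior weight of each path
    w = np.full(len(paths), 0.5)
    for t in range(1, T):
        if resets[t]:
            w *= 0.5
        else:
            stay = paths[:, t] == paths[:, t - 1]
            w *= np.where(stay, 1.0 - gamma, gamma)
    # per-trial emission factor of each path
    match = paths == outcomes_left[None, :]
    emis = np.where(match, c[None, :], 1.0 - c[None, :])

    b_pre = np.zeros(T)
    b_post = np.zeros(T)
    for t in range(T):
        w_pre = w * np.prod(emis[:, :t], axis=1)
        b_pre[t] = w_pre[paths[:, t] == 1].sum() / w_pre.sum()
        w_post = w_pre * emis[:, t]
        b_post[t] = w_post[paths[:, t] == 1].sum() / w_post.sum()
    return b_pre, b_post


def enumerate_choice_loglik(choices_left, outcomes_left, gamma, c_pos, c_neg,
                            inv_temp, resets=None):
    """Choice log likelihood built on the enumeration oracle's beliefs."""
    choices_left = np.asarray(choices_left, dtype=int)
    outcomes_left = np.asarray(outcomes_left, dtype=int)
    correct = choices_left == outcomes_left
    b_pre, _ = enumerate_beliefs(outcomes_left, correct, gamma, c_pos, c_neg, resets)
    p_left = 1.0 / (1.0 + np.exp(-inv_temp * (2.0 * b_pre - 1.0)))
    p = np.where(choices_left == 1, p_left, 1.0 - p_left)
    return float(np.log(p).sum())


# fixture builders shared with the package's validation batteries
from pupilhmm.validate import detection_rates, make_pupil_fixture  # noqa: E402,F401
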