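"""Trial-wise latent learning signals derived from state beliefs.

Two signals are extracted from the belief trajectory of the hidden-Markov
observer:

* **Bayesian surprise** — the Kullback-Leibler divergence of the
  post-outcome from the pre-outcome state belief,
  ``KL(post || pre) = sum_i P_post(i) ln(P_post(i) / P_pre(i))``,
  the warranted belief-update magnitude on a trial;
* **choice uncertainty** — the Shannon entropy of the state belief at
  choice time, ``H(b) = -(b ln b + (1-b) ln(1-b))``.

Both are in nats. For the trial-level pupil analyses they are z-scored
within participant x block.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import BeliefTrajectory

__all__ = [
    "bayesian_surprise",
    "choice_entropy",
    "zscore_within",
    "cube_root",
    "latent_table",
]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0 * ln 0 := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def bayesian_surprise(b_pre, b_post):
    """KL divergence (nats) of the post- from the pre-outcome belief.

    Raises if the update puts mass where the prior has none (divergence
    undefined).
    """
    scalar = np.ndim(b_pre) == 0 and np.ndim(b_post) == 0
    b_pre = np.atleast_1d(np.asarray(b_pre, dtype=float))
    b_post = np.atleast_1d(np.asarray(b_post, dtype=float))
    if np.any((b_pre < 0) | (b_pre > 1) | (b_post < 0) | (b_post > 1)):
        raise ValueError("beliefs must lie in [0, 1]")
    if np.any((b_pre == 0) & (b_post > 0)) or np.any((b_pre == 1) & (b_post < 1)):
        raise ValueError("divergence undefined: posterior mass where prior is zero")
    terms = np.zeros_like(b_post)
    for post, pre in ((b_post, b_pre), (1 - b_post, 1 - b_pre)):
        nz = post > 0
        terms[nz] += post[nz] * (np.log(post[nz]) - np.log(pre[nz]))
    out = np.maximum(terms, 0.0)  # clip tiny negative round-off
    return float(out[0]) if scalar else out


def choice_entropy(b):
    """Binary Shannon entropy of a state belief, in nats (max ln 2)."""
    scalar = np.ndim(b) == 0
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any((b < 0) | (b > 1)):
        raise ValueError("belief must lie in [0, 1]")
    h = -(_xlogx(b) + _xlogx(1 - b))
    h = np.clip(h, 0.0, np.log(2.0))
    return float(h[0]) if scalar else h


def zscore_within(values, groups) -> np.ndarray:
    """Standardize ``values`` to mean 0, SD 1 within each group.

    Groups with zero variance return zeros with a warning; singleton groups
    are rejected. Sample (ddof=1) standard deviation.
    """
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({"v": values, "g": pd.Series(list(groups))})
    out = np.empty_like(values)
    for _, idx in df.groupby("g", sort=False).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError("singleton group: cannot z-score")
        v = values[idx]
        sd = v.std(ddof=1)
        if sd == 0:
            warnings.warn("zero-variance group z-scored to all zeros", RuntimeWarning)
            out[idx] = 0.0
        else:
            out[idx] = (v - v.mean()) / sd
    return out


def cube_root(values):
    """Element-wise signed cube root (variance-stabilizing transform for
    Bayesian surprise)."""
    v = np.asarray(values, dtype=float)
    out = np.sign(v) * np.abs(v) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def latent_table(
    trajectory: BeliefTrajectory,
    participant: str,
    block_label: str,
    entropy_on: str = "pre",
) -> pd.DataFrame:
    """Per-trial surprise and entropy for one session, with within-session
    z-scores.

    ``entropy_on`` selects whether choice uncertainty is evaluated on the
    pre-outcome belief (default: the belief under which the choice was made)
    or the post-outcome belief.
    """
    if entropy_on not in ("pre", "post"):
        raise ValueError("entropy_on must be 'pre' or 'post'")
    b_pre = trajectory.b_pre
    b_post = trajectory.b_post
    surprise = np.atleast_1d(bayesian_surprise(b_pre, b_post))
    entropy = np.atleast_1d(choice_entropy(b_pre if entropy_on == "pre" else b_post))
    n = len(b_pre)
    group = [0] * n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z_s = zscore_within(surprise, group)
        z_e = zscore_within(entropy, group)
    return pd.DataFrame(
        {
            "participant": participant,
            "block": block_label,
            "trial": np.arange(1, n + 1),
            "surprise": surprise,
            "entropy": entropy,
            "z_surprise": z_s,
            "z_entropy": z_e,
        }
    )
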