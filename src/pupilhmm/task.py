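"""Two-block probabilistic prediction task environment.

The task presents a sequence of left/right-tilted stimuli. Within a segment
the majority side appears with a fixed probability (80:20 on low-risk
segments, 60:40 on high-risk segments); every ~20 trials the segment changes,
alternating risk level and flipping the majority side. The *volatile* block
hides these change points; the *cued* block announces them on screen and uses
the same change trials with the majority identity inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "RiskSchedule",
    "OutcomeSequence",
    "generate_schedule",
    "derive_cued_schedule",
    "sample_outcomes",
    "majority_stimulus",
    "schedule_table",
]

LOW_RISK_P = 0.8
HIGH_RISK_P = 0.6


@dataclass(frozen=True)
class Segment:
    """One constant-probability stretch of trials, 1-based inclusive bounds."""

    start: int
    end: int
    p_left: float
    risk_level: str  # "low" | "high"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RiskSchedule:
    """Per-trial generative probabilities of one task block."""

    block_label: str  # "volatile" | "cued"
    segments: list[Segment]
    n_trials: int
    change_trials: list[int] = field(default_factory=list)
    cued_flags: dict[int, bool] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("schedule has no segments")
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(f"segments do not tile trials (gap at {pos})")
            if seg.end < seg.start:
                raise ValueError("empty segment")
            pos = seg.end + 1
        if pos - 1 != self.n_trials:
            raise ValueError("segments do not cover n_trials")

    def segment_of(self, trial: int) -> Segment:
        if not 1 <= trial <= self.n_trials:
            raise IndexError(f"trial {trial} outside 1..{self.n_trials}")
        for seg in self.segments:
            if seg.start <= trial <= seg.end:
                return seg
        raise AssertionError("unreachable: segments tile all trials")

    def p_left_per_trial(self) -> np.ndarray:
        out = np.empty(self.n_trials)
        for seg in self.segments:
            out[seg.start - 1 : seg.end] = seg.p_left
        return out

    def risk_per_trial(self) -> np.ndarray:
        out = np.empty(self.n_trials, dtype=object)
        for seg in self.segments:
            out[seg.start - 1 : seg.end] = seg.risk_level
        return out


@dataclass
class OutcomeSequence:
    """One realized stimulus sequence drawn from a schedule."""

    stimuli: list[str]  # "left" | "right" per trial
    schedule_ref: str
    seed: int

    def __len__(self) -> int:
        return len(self.stimuli)


def _risk_p(risk_level: str) -> float:
    return LOW_RISK_P if risk_level == "low" else HIGH_RISK_P


def generate_schedule(
    n_trials: int = 160,
    base_length: int = 20,
    jitter: int = 4,
    risk_order: list[str] | None = None,
    seed: int = 0,
    block_label: str = "volatile",
    start_majority: str = "left",
) -> RiskSchedule:
    """Generate a risk schedule with change points every ``base_length ± jitter``.

    Segment lengths are drawn uniformly from the integers
    ``[base_length - jitter, base_length + jitter]``; the final segment is
    truncated at ``n_trials``. Consecutive segments follow ``risk_order``
    cyclically (default alternation low/high) and flip the majority side at
    every change.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if jitter < 0 or base_length - jitter < 1:
        raise ValueError("require 0 <= jitter < base_length")
    if risk_order is None:
        risk_order = ["low", "high"]
    rng = np.random.default_rng(seed)

    segments: list[Segment] = []
    change_trials: list[int] = []
    pos = 1
    majority_left = start_majority == "left"
    i = 0
    while pos <= n_trials:
        length = int(rng.integers(base_length - jitter, base_length + jitter + 1))
        end = min(pos + length - 1, n_trials)
        risk = risk_order[i % len(risk_order)]
        p_maj = _risk_p(risk)
        p_left = p_maj if majority_left else 1.0 - p_maj
        segments.append(Segment(pos, end, p_left, risk))
        if pos > 1:
            change_trials.append(pos)
        pos = end + 1
        majority_left = not majority_left
        i += 1
    return RiskSchedule(
        block_label=block_label,
        segments=segments,
        n_trials=n_trials,
        change_trials=change_trials,
        cued_flags={t: False for t in change_trials},
        seed=seed,
    )


def derive_cued_schedule(volatile: RiskSchedule) -> RiskSchedule:
    """Derive the cued block from a volatile schedule.

    Change trials and risk levels are identical; the majority side is
    inverted (``p_left -> 1 - p_left``) and every change point is cued.
    """
    segments = [replace(s, p_left=round(1.0 - s.p_left, 12)) for s in volatile.segments]
    return RiskSchedule(
        block_label="cued",
        segments=segments,
        n_trials=volatile.n_trials,
        change_trials=list(volatile.change_trials),
        cued_flags={t: True for t in volatile.change_trials},
        seed=volatile.seed,
    )


def sample_outcomes(schedule: RiskSchedule, seed: int = 0) -> OutcomeSequence:
    """Draw a per-trial stimulus sequence with each segment's ``p_left``."""
    rng = np.random.default_rng(seed)
    p = schedule.p_left_per_trial()
    draws = rng.random(schedule.n_trials)
    stimuli = ["left" if u < pl else "right" for u, pl in zip(draws, p)]
    return OutcomeSequence(
        stimuli=stimuli,
        schedule_ref=f"{schedule.block_label}:{schedule.seed}",
        seed=seed,
    )


def majority_stimulus(schedule: RiskSchedule, trial: int) -> str:
    """Majority side of the segment containing ``trial`` (new segment on a
    change boundary)."""
    seg = schedule.segment_of(trial)
    return "left" if seg.p_left > 0.5 else "right"


def schedule_table(schedule: RiskSchedule, outcomes: OutcomeSequence | None = None) -> pd.DataFrame:
    """One-row-per-trial delimited-text view of a schedule (and outcomes)."""
    trials = np.arange(1, schedule.n_trials + 1)
    changes = set(schedule.change_trials)
    df = pd.DataFrame(
        {
            "block": schedule.block_label,
            "trial": trials,
            "p_left": schedule.p_left_per_trial(),
            "risk_level": schedule.risk_per_trial(),
            "is_change": [t in changes for t in trials],
            "is_cued_change": [schedule.cued_flags.get(t, False) for t in trials],
        }
    )
    if outcomes is not None:
        if len(outcomes) != schedule.n_trials:
            raise ValueError("outcome sequence length does not match schedule")
        df["stimulus"] = outcomes.stimuli
    return df
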