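"""Pupillometry preprocessing chain for 500 Hz eye-tracker sample reports.

Stages, in order: velocity-based artifact (blink) detection with per-trace
adaptive thresholds, cubic-spline interpolation of artifact gaps (gaps
longer than 1,000 ms are treated as missing instead), zero-phase low-pass
Butterworth smoothing (3 Hz cutoff), per-block z-scoring, and per-trial
epoching around outcome onsets with baseline correction (mean of the 500 ms
preceding the onset) over a 2,000 ms outcome window. Trials with more than
50% interpolated-or-missing samples in either window fail QC. The trial-wise
readout is the maximum baseline-corrected dilation in the outcome window
(signed square root provided for the statistical models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

__all__ = [
    "PupilTrace",
    "CleanedTrace",
    "PupilEpochTable",
    "detect_artifacts",
    "interpolate_artifacts",
    "smooth",
    "normalize_block",
    "epoch_trials",
    "preprocess_trace",
]


@dataclass
class PupilTrace:
    """Raw sample-level pupil recording of one participant x block."""

    time_ms: np.ndarray
    diameter: np.ndarray
    block_label: str = ""
    onsets_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    participant: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time_ms.shape != self.diameter.shape:
            raise ValueError("time and diameter must have equal length")
        steps = np.diff(self.time_ms)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time must increase at a uniform sampling interval")
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=float)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if len(self.time_ms) > 1 else 2.0

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass
class CleanedTrace:
    """Pupil trace after interpolation / smoothing / normalization."""

    time_ms: np.ndarray
    diameter: np.ndarray
    interpolated_mask: np.ndarray
    missing_mask: np.ndarray
    block_label: str = ""
    onsets_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    participant: str = ""
    z_diameter: np.ndarray | None = None

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if len(self.time_ms) > 1 else 2.0

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass
class PupilEpochTable:
    """Per-trial baseline-corrected epochs, QC flags, and max dilation."""

    trials: pd.DataFrame
    epochs: list  # per-trial corrected outcome-window arrays (NaN where missing)
    baseline_ms: float
    window_ms: float


def _runs(mask: np.ndarray):
    """Yield (start, end_exclusive) for each contiguous True run."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_artifacts(
    trace: PupilTrace,
    velocity_k: float = 6.0,
    margin_pre_ms: float = 60.0,
    margin_post_ms: float = 120.0,
    min_velocity: float = 0.05,
) -> np.ndarray:
    """Flag blink/artifact samples from the pupil signal's velocity.

    Samples whose absolute first difference exceeds
    ``median + velocity_k * MAD`` of the per-trace velocity distribution are
    flagged, as are zero or non-finite diameters; flagged runs are expanded
    by the pre/post margins. Thresholds are computed per trace, i.e., per
    individual recording. ``min_velocity`` (diameter units per sample) is an
    absolute lower bound on the threshold: blink transitions move the pupil
    signal orders of magnitude faster than physiological change, and the
    floor keeps near-noiseless recordings from having their slow
    event-evoked responses flagged.
    """
    d = trace.diameter
    if len(d) < 3:
        raise ValueError("trace too short for artifact detection")
    flagged = (d <= 0) | ~np.isfinite(d)
    v = np.abs(np.diff(d))
    v = np.where(np.isfinite(v), v, np.inf)
    finite_v = v[np.isfinite(v)]
    if finite_v.size:
        med = np.median(finite_v)
        mad = np.median(np.abs(finite_v - med))
        thr = max(med + velocity_k * mad, min_velocity)
        fast = v > thr
        # artifact transitions are sustained; an isolated fast sample is
        # almost always a noise excursion past the threshold, so require a
        # fast neighbor before flagging
        neighbor = np.zeros_like(fast)
        neighbor[:-1] |= fast[1:]
        neighbor[1:] |= fast[:-1]
        fast &= neighbor
        flagged[:-1] |= fast
        flagged[1:] |= fast
    pre = int(round(margin_pre_ms / trace.dt_ms))
    post = int(round(margin_post_ms / trace.dt_ms))
    out = flagged.copy()
    for s, e in _runs(flagged):
        out[max(0, s - pre) : min(len(out), e + post)] = True
    if out.all():
        raise ValueError("entire trace flagged as artifact; trace unusable")
    return out


def interpolate_artifacts(
    trace: PupilTrace,
    mask: np.ndarray,
    max_gap_ms: float = 1000.0,
    flank_ms: float = 100.0,
) -> CleanedTrace:
    """Replace flagged gaps by cubic-spline interpolation over flanking
    clean samples; gaps longer than ``max_gap_ms`` (and gaps at the trace
    boundary without a flank) become missing instead.

    The spline is anchored on denoised control points — two per side, each
    the mean of a ``flank_ms / 2`` window of clean samples — rather than on
    raw samples: an interpolating cubic through noisy flank samples can
    overshoot by many signal units inside a long gap.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != trace.diameter.shape:
        raise ValueError("mask length must match trace")
    d = trace.diameter.astype(float).copy()
    interp = np.zeros_like(mask)
    missing = np.zeros_like(mask)
    w = max(2, int(round(flank_ms / (2 * trace.dt_ms))))  # control window, samples
    clean_idx = np.flatnonzero(~mask)
    for s, e in _runs(mask):
        gap_ms = (e - s) * trace.dt_ms
        j = np.searchsorted(clean_idx, s)  # clean_idx[:j] < s, clean_idx[j:] >= e
        if gap_ms > max_gap_ms or j == 0 or j == len(clean_idx):
            missing[s:e] = True
            d[s:e] = np.nan
            continue
        xs, ys = [], []
        for window in (clean_idx[max(0, j - 2 * w) : max(0, j - w)],
                       clean_idx[max(0, j - w) : j],
                       clean_idx[j : j + w],
                       clean_idx[j + w : j + 2 * w]):
            if window.size:
                xs.append(trace.time_ms[window].mean())
                ys.append(trace.diameter[window].mean())
        if len(xs) >= 4:
            curve = CubicSpline(xs, ys)
        else:  # thin flank: fall back to the straight line through the means
            coeff = np.polyfit(xs, ys, 1)
            curve = np.poly1d(coeff)
        d[s:e] = curve(trace.time_ms[s:e])
        interp[s:e] = True
    return CleanedTrace(
        time_ms=trace.time_ms,
        diameter=d,
        interpolated_mask=interp,
        missing_mask=missing,
        block_label=trace.block_label,
        onsets_ms=trace.onsets_ms,
        participant=trace.participant,
    )


def smooth(trace: CleanedTrace, cutoff_hz: float = 3.0, order: int = 3) -> CleanedTrace:
    """Zero-phase low-pass Butterworth smoothing; missing spans untouched.

    The filter is applied forward-backward (``filtfilt``) separately within
    each contiguous non-missing segment so the output has no phase delay.
    """
    nyquist = trace.fs / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    d = trace.diameter.copy()
    default_padlen = 3 * max(len(a), len(b))
    for s, e in _runs(~trace.missing_mask):
        seg = d[s:e]
        if len(seg) <= order + 1:
            continue
        padlen = min(default_padlen, len(seg) - 1)
        d[s:e] = filtfilt(b, a, seg, padlen=padlen)
    return CleanedTrace(
        time_ms=trace.time_ms,
        diameter=d,
        interpolated_mask=trace.interpolated_mask,
        missing_mask=trace.missing_mask,
        block_label=trace.block_label,
        onsets_ms=trace.onsets_ms,
        participant=trace.participant,
        z_diameter=trace.z_diameter,
    )


def normalize_block(trace: CleanedTrace) -> CleanedTrace:
    """z-score the smoothed signal over non-missing samples of the block."""
    good = ~trace.missing_mask
    if good.sum() < 2:
        raise ValueError("need at least 2 non-missing samples to z-score")
    v = trace.diameter[good]
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance trace cannot be z-scored")
    z = np.full_like(trace.diameter, np.nan)
    z[good] = (trace.diameter[good] - v.mean()) / sd
    out = CleanedTrace(
        time_ms=trace.time_ms,
        diameter=trace.diameter,
        interpolated_mask=trace.interpolated_mask,
        missing_mask=trace.missing_mask,
        block_label=trace.block_label,
        onsets_ms=trace.onsets_ms,
        participant=trace.participant,
        z_diameter=z,
    )
    return out


def epoch_trials(
    trace: CleanedTrace,
    onsets_ms: np.ndarray | None = None,
    baseline_ms: float = 500.0,
    window_ms: float = 2000.0,
) -> PupilEpochTable:
    """Epoch the normalized trace around outcome onsets.

    Windows are half-open: baseline ``[onset - baseline_ms, onset)``,
    outcome ``[onset, onset + window_ms)``. A trial is valid only if both
    windows have at most 50% interpolated-or-missing samples; the maximum of
    the baseline-corrected signal in the outcome window is the trial
    readout, with its signed square root.
    """
    if trace.z_diameter is None:
        raise ValueError("trace must be normalized before epoching")
    if onsets_ms is None:
        onsets_ms = trace.onsets_ms
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    dt = trace.dt_ms
    n = len(trace.time_ms)
    t0 = trace.time_ms[0]
    corrupted = trace.interpolated_mask | trace.missing_mask
    rows = []
    epochs = []
    for k, onset in enumerate(onsets_ms, start=1):
        i_on = int(round((onset - t0) / dt))
        i_b0 = i_on - int(round(baseline_ms / dt))
        i_e1 = i_on + int(round(window_ms / dt))
        if i_b0 < 0 or i_e1 > n:
            rows.append(
                dict(trial=k, onset_ms=onset, baseline=np.nan,
                     fraction_interpolated_baseline=np.nan,
                     fraction_interpolated_outcome=np.nan, valid=False,
                     max_dilation=np.nan, sqrt_max_dilation=np.nan)
            )
            epochs.append(np.full(max(i_e1 - i_on, 0), np.nan))
            continue
        zb = trace.z_diameter[i_b0:i_on]
        zo = trace.z_diameter[i_on:i_e1]
        frac_b = float(corrupted[i_b0:i_on].mean())
        frac_o = float(corrupted[i_on:i_e1].mean())
        baseline = float(np.nanmean(zb)) if np.any(np.isfinite(zb)) else np.nan
        epoch = zo - baseline
        valid = frac_b <= 0.5 and frac_o <= 0.5 and np.isfinite(baseline)
        if valid and np.any(np.isfinite(epoch)):
            mx = float(np.nanmax(epoch))
            smx = float(np.sign(mx) * np.sqrt(abs(mx)))
        else:
            valid, mx, smx = False, np.nan, np.nan
        rows.append(
            dict(trial=k, onset_ms=onset, baseline=baseline,
                 fraction_interpolated_baseline=frac_b,
                 fraction_interpolated_outcome=frac_o, valid=valid,
                 max_dilation=mx, sqrt_max_dilation=smx)
        )
        epochs.append(epoch)
    return PupilEpochTable(
        trials=pd.DataFrame(rows), epochs=epochs,
        baseline_ms=baseline_ms, window_ms=window_ms,
    )


def preprocess_trace(
    trace: PupilTrace,
    velocity_k: float = 6.0,
    margin_pre_ms: float = 60.0,
    margin_post_ms: float = 120.0,
    cutoff_hz: float = 3.0,
    baseline_ms: float = 500.0,
    window_ms: float = 2000.0,
) -> tuple[CleanedTrace, PupilEpochTable, dict]:
    """Run the full preprocessing chain on one trace.

    Returns the cleaned, normalized trace, the per-trial epoch table, and a
    per-stage log of counts (flagged, interpolated, missing samples and
    excluded trials).
    """
    mask = detect_artifacts(trace, velocity_k, margin_pre_ms, margin_post_ms)
    cleaned = interpolate_artifacts(trace, mask)
    smoothed = smooth(cleaned, cutoff_hz)
    normed = normalize_block(smoothed)
    table = epoch_trials(normed, baseline_ms=baseline_ms, window_ms=window_ms)
    log = {
        "n_samples": len(trace.diameter),
        "n_flagged": int(mask.sum()),
        "n_interpolated": int(cleaned.interpolated_mask.sum()),
        "n_missing": int(cleaned.missing_mask.sum()),
        "n_trials": len(table.trials),
        "n_excluded_trials": int((~table.trials["valid"]).sum()),
    }
    return normed, table, log
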