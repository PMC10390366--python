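import numpy as np
import pytest

from helpers import detection_rates, make_pupil_fixture
from pupilhmm.pupil import (
    CleanedTrace,
    PupilTrace,
    detect_artifacts,
    epoch_trials,
    interpolate_artifacts,
    normalize_block,
    preprocess_trace,
    smooth,
)


def flat_trace(n=5000, value=5.0):
    return PupilTrace(time_ms=np.arange(n) * 2.0, diameter=np.full(n, value))


class TestDetectArtifacts:
    def test_constant_trace_empty_mask(self):
        assert not detect_artifacts(flat_trace()).any()

    def test_synthetic_blink_fully_covered(self):
        trace, blink_mask, _ = make_pupil_fixture(seed=1, n_trials=10, n_blinks=3)
        mask = detect_artifacts(trace)
        assert mask[blink_mask].all()

    def test_detection_benchmark_small(self):
        sens, false = [], []
        for seed in range(10):
            trace, blink_mask, _ = make_pupil_fixture(seed=seed, n_trials=15, n_blinks=5)
            mask = detect_artifacts(trace)
            s, f = detection_rates(mask, blink_mask)
            sens.append(s)
            false.append(f)
        assert np.mean(sens) >= 0.95
        assert np.mean(false) <= 0.05

    def test_all_flagged_trace_rejected(self):
        trace = PupilTrace(time_ms=np.arange(100) * 2.0, diameter=np.zeros(100))
        with pytest.raises(ValueError):
            detect_artifacts(trace)


class TestInterpolation:
    def test_gap_in_linear_ramp_recovered(self):
        n = 2000
        trace = PupilTrace(time_ms=np.arange(n) * 2.0, diameter=np.linspace(3, 7, n))
        mask = np.zeros(n, bool)
        mask[800:1050] = True  # 500 ms gap
        cleaned = interpolate_artifacts(trace, mask)
        np.testing.assert_allclose(cleaned.diameter, np.linspace(3, 7, n), atol=1e-8)
        assert cleaned.interpolated_mask[800:1050].all()
        assert not cleaned.missing_mask.any()

    def test_long_gap_becomes_missing(self):
        n = 3000
        trace = PupilTrace(time_ms=np.arange(n) * 2.0, diameter=np.full(n, 5.0))
        mask = np.zeros(n, bool)
        mask[500:1101] = True  # 1202 ms
        cleaned = interpolate_artifacts(trace, mask)
        assert cleaned.missing_mask[500:1101].all()
        assert not cleaned.interpolated_mask.any()
        assert np.isnan(cleaned.diameter[500:1101]).all()

    def test_empty_mask_identity(self):
        trace, _, _ = make_pupil_fixture(seed=2, n_trials=5, n_blinks=0)
        cleaned = interpolate_artifacts(trace, np.zeros(len(trace.diameter), bool))
        np.testing.assert_array_equal(cleaned.diameter, trace.diameter)

    def test_boundary_gap_without_flank_is_missing(self):
        n = 1000
        trace = PupilTrace(time_ms=np.arange(n) * 2.0, diameter=np.full(n, 5.0))
        mask = np.zeros(n, bool)
        mask[:100] = True
        cleaned = interpolate_artifacts(trace, mask)
        assert cleaned.missing_mask[:100].all()


class TestSmoothing:
    def _sine_trace(self, freq_hz, n=25_000):
        t = np.arange(n) * 2.0
        d = 5.0 + np.sin(2 * np.pi * freq_hz * t / 1000.0)
        return CleanedTrace(
            time_ms=t, diameter=d,
            interpolated_mask=np.zeros(n, bool), missing_mask=np.zeros(n, bool),
        )

    def test_passband_amplitude_preserved(self):
        out = smooth(self._sine_trace(0.5), cutoff_hz=3.0)
        core = slice(2500, -2500)
        ratio = (out.diameter[core] - 5).std() / (self._sine_trace(0.5).diameter[core] - 5).std()
        assert abs(ratio - 1) < 0.02

    def test_stopband_attenuation(self):
        out = smooth(self._sine_trace(25.0), cutoff_hz=3.0)
        core = slice(2500, -2500)
        ratio = (out.diameter[core] - 5).std() / (self._sine_trace(25.0).diameter[core] - 5).std()
        assert ratio < 0.1

    def test_constant_unchanged(self):
        n = 5000
        trace = CleanedTrace(
            time_ms=np.arange(n) * 2.0, diameter=np.full(n, 4.2),
            interpolated_mask=np.zeros(n, bool), missing_mask=np.zeros(n, bool),
        )
        np.testing.assert_allclose(smooth(trace).diameter, 4.2, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            smooth(self._sine_trace(1.0), cutoff_hz=300.0)


class TestNormalize:
    def _trace(self, d, missing=None):
        n = len(d)
        return CleanedTrace(
            time_ms=np.arange(n) * 2.0, diameter=np.asarray(d, float),
            interpolated_mask=np.zeros(n, bool),
            missing_mask=np.zeros(n, bool) if missing is None else missing,
        )

    def test_moments_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(5, 0.3, 4000)
        z1 = normalize_block(self._trace(d)).z_diameter
        z2 = normalize_block(self._trace(3.7 * d + 11.0)).z_diameter
        assert z1.mean() == pytest.approx(0, abs=1e-12)
        assert z1.std(ddof=1) == pytest.approx(1, abs=1e-12)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_missing_stays_missing(self):
        d = np.random.default_rng(1).normal(5, 0.3, 1000)
        missing = np.zeros(1000, bool)
        missing[100:200] = True
        z = normalize_block(self._trace(d, missing)).z_diameter
        assert np.isnan(z[100:200]).all()
        assert np.isfinite(z[~missing]).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalize_block(self._trace(np.full(100, 3.0)))


class TestEpoching:
    def _normalized(self, z, onsets, interp=None, missing=None):
        n = len(z)
        return CleanedTrace(
            time_ms=np.arange(n) * 2.0, diameter=np.asarray(z, float),
            interpolated_mask=np.zeros(n, bool) if interp is None else interp,
            missing_mask=np.zeros(n, bool) if missing is None else missing,
            onsets_ms=np.asarray(onsets, float), z_diameter=np.asarray(z, float),
        )

    def test_baseline_ramp_fixture(self):
        # baseline 1.0, ramp peaking at 1.8 in the outcome window -> max 0.8
        n = 2000  # 4 s
        z = np.full(n, 1.0)
        onset = 1500.0  # sample 750
        ramp = np.linspace(1.0, 1.8, 500)
        z[750:1250] = ramp
        table = epoch_trials(self._normalized(z, [onset]))
        row = table.trials.iloc[0]
        assert row["baseline"] == pytest.approx(1.0)
        assert row["max_dilation"] == pytest.approx(0.8, abs=1e-9)
        assert row["sqrt_max_dilation"] == pytest.approx(np.sqrt(0.8), abs=1e-9)
        assert row["valid"]

    def test_baseline_window_mean_zero(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 3000)
        table = epoch_trials(self._normalized(z, [1000.0, 3500.0]))
        for k, epoch in enumerate(table.epochs):
            onset_idx = int(table.trials.iloc[k]["onset_ms"] / 2)
            corrected_baseline = (
                z[onset_idx - 250 : onset_idx] - table.trials.iloc[k]["baseline"]
            )
            assert abs(corrected_baseline.mean()) < 1e-10

    def test_corrupted_baseline_fails_qc(self):
        n = 2000
        interp = np.zeros(n, bool)
        interp[500:750] = True  # 100% of the 500 ms baseline window
        table = epoch_trials(self._normalized(np.ones(n), [1500.0], interp=interp))
        assert not table.trials.iloc[0]["valid"]
        assert table.trials.iloc[0]["fraction_interpolated_baseline"] == pytest.approx(1.0)

    def test_sixty_percent_interpolated_outcome_invalid(self):
        n = 2000
        interp = np.zeros(n, bool)
        interp[750:1350] = True  # 60% of the 2,000 ms outcome window
        table = epoch_trials(self._normalized(np.ones(n), [1500.0], interp=interp))
        assert table.trials.iloc[0]["fraction_interpolated_outcome"] == pytest.approx(0.6)
        assert not table.trials.iloc[0]["valid"]

    def test_qc_monotone_in_corruption(self):
        n = 2000
        previous_valid = True
        for frac in (0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0):
            interp = np.zeros(n, bool)
            interp[750 : 750 + int(1000 * frac)] = True
            table = epoch_trials(self._normalized(np.ones(n), [1500.0], interp=interp))
            valid = bool(table.trials.iloc[0]["valid"])
            assert not (valid and not previous_valid)  # never invalid -> valid
            previous_valid = valid

    def test_incomplete_window_marked_missing(self):
        table = epoch_trials(self._normalized(np.ones(1000), [100.0]))
        assert not table.trials.iloc[0]["valid"]
        assert np.isnan(table.trials.iloc[0]["max_dilation"])


class TestFullChain:
    def test_amplitude_recovery(self):
        trace, _, amplitudes = make_pupil_fixture(seed=7, n_trials=50, n_blinks=6)
        _, table, _ = preprocess_trace(trace)
        ok = table.trials["valid"].to_numpy()
        r = np.corrcoef(amplitudes[ok], table.trials.loc[ok, "max_dilation"])[0, 1]
        assert r > 0.9

    def test_mask_idempotence_after_cleaning(self):
        trace, _, _ = make_pupil_fixture(seed=8, n_trials=20, n_blinks=4)
        cleaned, _, _ = preprocess_trace(trace)
        # longest contiguous non-missing run keeps the time grid uniform
        good = ~cleaned.missing_mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
        runs = list(zip(edges[::2], edges[1::2]))
        s, e = max(runs, key=lambda r: r[1] - r[0])
        retrace = PupilTrace(time_ms=cleaned.time_ms[s:e], diameter=cleaned.diameter[s:e])
        # re-detection on the cleaned, smoothed signal should be near-silent
        assert detect_artifacts(retrace).mean() < 0.01

    def test_stage_log_counts(self):
        trace, blink_mask, _ = make_pupil_fixture(seed=9, n_trials=10, n_blinks=3)
        _, table, log = preprocess_trace(trace)
        assert log["n_flagged"] >= blink_mask.sum()
        assert log["n_trials"] == 10
        assert log["n_excluded_trials"] == int((~table.trials["valid"]).sum())
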