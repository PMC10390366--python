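"""Validation batteries: recovery studies and benchmark fixtures.

These are the package's standing evaluation suites — parameter and model
recovery for the belief models, directional checks on the latent signals,
a blink-detection benchmark with ground-truth fixtures, and end-to-end
planted-effect recovery through the full pipeline. They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from .fitting import compare_models, fit_mle
from .latents import latent_table
from .models import HMMRPParams, RLParams, WSLSParams, filter_beliefs, simulate_agent
from .pipeline import study_trial_table
from .pupil import PupilTrace, detect_artifacts, preprocess_trace
from .stats import lme_pupil_latent
from .synth import StudyConfig, simulate_study
from .task import derive_cued_schedule, generate_schedule, sample_outcomes

__all__ = [
    "make_pupil_fixture",
    "detection_rates",
    "parameter_recovery",
    "model_recovery",
    "latent_direction_battery",
    "pupil_detection_benchmark",
    "planted_effect_power",
    "null_false_positive_rate",
    "schedule_battery",
]


# ---------------------------------------------------------------------------
# pupil fixtures with ground truth


def make_pupil_fixture(
    seed=0,
    n_trials=40,
    trial_ms=4000.0,
    onset_in_trial_ms=1500.0,
    dt_ms=2.0,
    baseline=5.0,
    noise_sd=0.05,
    amplitudes=None,
    n_blinks=8,
    drift_amp=0.1,
):
    """Synthetic pupil trace with known event amplitudes and blink spans.

    Returns ``(trace, true_blink_mask, amplitudes)`` where the mask marks
    exactly the samples overwritten by blink artifacts.
    """
    rng = np.random.default_rng(seed)
    n = int(round(n_trials * trial_ms / dt_ms))
    time_ms = np.arange(n) * dt_ms
    onsets = np.arange(n_trials) * trial_ms + onset_in_trial_ms
    if amplitudes is None:
        amplitudes = rng.uniform(0.1, 0.6, n_trials)
    amplitudes = np.asarray(amplitudes, dtype=float)

    t = np.arange(dt_ms, 3000.0 + dt_ms, dt_ms)
    kernel = (t / 930.0) ** 10.1 * np.exp(10.1 * (1 - t / 930.0))
    kernel /= kernel.max()

    d = np.full(n, baseline)
    d += drift_amp * np.sin(2 * np.pi * time_ms / 90_000.0 + rng.uniform(0, 2 * np.pi))
    for k, onset in enumerate(onsets):
        i0 = int(round(onset / dt_ms))
        i1 = min(i0 + len(kernel), n)
        d[i0:i1] += amplitudes[k] * kernel[: i1 - i0]
    if noise_sd > 0:
        d += rng.normal(0, noise_sd, n)

    blink_mask = np.zeros(n, dtype=bool)
    collapse = int(round(8 / dt_ms))
    recover = int(round(40 / dt_ms))
    for _ in range(n_blinks):
        floor_len = int(round(rng.uniform(100, 200) / dt_ms))
        span = collapse + floor_len + recover
        start = int(rng.integers(0, n - span - 1))
        pre_val, post_val = d[start], d[start + span]
        d[start : start + collapse] = np.linspace(pre_val, 0, collapse, endpoint=False)
        d[start + collapse : start + collapse + floor_len] = 0.0
        r0 = start + collapse + floor_len
        d[r0 : r0 + recover] = np.linspace(0, post_val, recover, endpoint=False)
        blink_mask[start : start + span] = True
    trace = PupilTrace(time_ms=time_ms, diameter=d, block_label="volatile", onsets_ms=onsets)
    return trace, blink_mask, amplitudes


def detection_rates(mask, blink_mask, dt_ms=2.0, guard_pre_ms=60.0, guard_post_ms=120.0):
    """Sensitivity on true blink samples; false-flag rate on clean samples
    outside a guard zone around the true blinks (the detector deliberately
    expands its flags by safety margins)."""
    guard = blink_mask.copy()
    pre = int(round(guard_pre_ms / dt_ms))
    post = int(round(guard_post_ms / dt_ms))
    idx = np.flatnonzero(np.diff(np.concatenate(([0], blink_mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        guard[max(0, s - pre) : min(len(guard), e + post)] = True
    sensitivity = mask[blink_mask].mean() if blink_mask.any() else 1.0
    clean = ~guard
    false_rate = mask[clean].mean() if clean.any() else 0.0
    return float(sensitivity), float(false_rate)


# ---------------------------------------------------------------------------
# recovery batteries


def parameter_recovery(n_agents: int = 50, n_trials: int = 320, seed: int = 0) -> dict:
    """Simulate HMM_RP agents over a gamma range and refit them.

    Reports the Spearman correlation between generating and recovered
    transition probabilities and the recovery rate of the feedback-asymmetry
    sign among agents with ``|c_pos - c_neg| >= 0.15``.
    """
    rng = np.random.default_rng(seed)
    sched = generate_schedule(n_trials, 20, 4, seed=int(rng.integers(2**31)))
    true_g, est_g = [], []
    sign_ok = sign_n = 0
    for i in range(n_agents):
        g = rng.uniform(0.02, 0.40)
        cp, cn = rng.uniform(0.55, 0.95, 2)
        it = float(np.exp(rng.normal(np.log(5.0), 0.25)))
        params = HMMRPParams(g, cp, cn, it)
        out = sample_outcomes(sched, int(rng.integers(2**31)))
        sess = simulate_agent("hmm_rp", params, sched, out, seed=int(rng.integers(2**31)))
        fit = fit_mle("hmm_rp", sess, n_starts=10, seed=i)
        true_g.append(g)
        est_g.append(fit.params["gamma"])
        if abs(cp - cn) >= 0.15:
            sign_n += 1
            sign_ok += int(np.sign(fit.params["c_pos"] - fit.params["c_neg"]) == np.sign(cp - cn))
    return {
        "gamma_spearman": float(spearmanr(true_g, est_g).statistic),
        "asymmetry_sign_rate": sign_ok / sign_n if sign_n else np.nan,
        "n_agents": n_agents,
        "n_asymmetric": sign_n,
    }


def _draw_params(model: str, rng) -> object:
    it = float(np.exp(rng.normal(np.log(5.0), 0.25)))
    if model == "wsls":
        return WSLSParams(rng.uniform(0.7, 0.95), rng.uniform(0.6, 0.9))
    if model == "rescorla_wagner":
        return RLParams("rescorla_wagner", it, alpha=rng.uniform(0.1, 0.5))
    if model == "hmm_rp":
        return HMMRPParams(rng.uniform(0.05, 0.35), rng.uniform(0.65, 0.9),
                           rng.uniform(0.65, 0.9), it)
    raise KeyError(model)


def model_recovery(
    n_cohorts: int = 20,
    n_agents: int = 20,
    n_trials: int = 160,
    seed: int = 0,
    models=("wsls", "rescorla_wagner", "hmm_rp"),
    n_starts: int = 4,
) -> dict:
    """Generate cohorts from each model family and ask the summed-BIC
    comparison to identify the generating family."""
    rng = np.random.default_rng(seed)
    wins = {m: 0 for m in models}
    for generator in models:
        for _ in range(n_cohorts):
            sched = generate_schedule(n_trials, 20, 4, seed=int(rng.integers(2**31)))
            fits_by_model = {m: [] for m in models}
            for a in range(n_agents):
                params = _draw_params(generator, rng)
                out = sample_outcomes(sched, int(rng.integers(2**31)))
                sess = simulate_agent(
                    generator, params, sched, out,
                    seed=int(rng.integers(2**31)), participant=f"a{a}",
                )
                for m in models:
                    fits_by_model[m].append(
                        fit_mle(m, sess, n_starts=n_starts, seed=int(rng.integers(2**31)))
                    )
            if compare_models(fits_by_model).best_model == generator:
                wins[generator] += 1
    rates = {m: wins[m] / n_cohorts for m in models}
    return {
        "per_model_rate": rates,
        "overall_rate": float(np.mean(list(rates.values()))),
        "n_cohorts": n_cohorts,
        "n_agents": n_agents,
    }


def latent_direction_battery(n_sessions: int = 100, n_trials: int = 160,
                             seed: int = 0, burn_in: int = 5) -> dict:
    """Directional structure of the latent signals over simulated sessions.

    For each simulated participant, beliefs are filtered with the study's
    block-specific subjective volatilities (transition probability around
    0.22 in the volatile block, around 0.10 with announced-change resets in
    the cued block). The battery computes mean belief entropy on high- vs
    low-risk trials (excluding the first ``burn_in`` trials of each segment)
    and mean Bayesian surprise in the volatile vs the cued block; sign tests
    aggregate over sessions.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    ent_wins = surp_wins = 0
    ent_diffs, surp_diffs = [], []
    for i in range(n_sessions):
        vol = generate_schedule(n_trials, 20, 4, seed=int(rng.integers(2**31)))
        cued = derive_cued_schedule(vol)
        z = rng.standard_normal()
        gamma = {
            "volatile": float(expit(logit(0.22) + 0.4 * z)),
            "cued": float(expit(logit(0.10) + 0.4 * z)),
        }
        cp, cn = rng.uniform(0.7, 0.9, 2)
        it = float(np.exp(rng.normal(np.log(5.0), 0.25)))
        latents = {}
        for sched, resets in ((vol, None), (cued, cued.change_trials)):
            params = HMMRPParams(gamma[sched.block_label], cp, cn, it)
            out = sample_outcomes(sched, int(rng.integers(2**31)))
            sess = simulate_agent("hmm_rp", params, sched, out,
                                  seed=int(rng.integers(2**31)), reset_trials=resets)
            traj = filter_beliefs(sess, params, resets)
            latents[sched.block_label] = latent_table(traj, "a", sched.block_label)

        # risk labels and per-segment burn-in on the volatile block
        risk = vol.risk_per_trial()
        seg_trial = np.concatenate([np.arange(1, len(s) + 1) for s in vol.segments])
        keep = seg_trial > burn_in
        ent = latents["volatile"]["entropy"].to_numpy()
        hi = ent[keep & (risk == "high")].mean()
        lo = ent[keep & (risk == "low")].mean()
        ent_diffs.append(hi - lo)
        ent_wins += int(hi > lo)

        sv = latents["volatile"]["surprise"].mean()
        sc = latents["cued"]["surprise"].mean()
        surp_diffs.append(sv - sc)
        surp_wins += int(sv > sc)
    return {
        "entropy_high_minus_low": float(np.mean(ent_diffs)),
        "surprise_volatile_minus_cued": float(np.mean(surp_diffs)),
        "entropy_sign_p": float(binomtest(ent_wins, n_sessions, 0.5, "greater").pvalue),
        "surprise_sign_p": float(binomtest(surp_wins, n_sessions, 0.5, "greater").pvalue),
        "n_sessions": n_sessions,
    }


def pupil_detection_benchmark(n_traces: int = 100, n_trials: int = 15, seed: int = 0) -> dict:
    """Blink-detection sensitivity/false-flag rates and amplitude recovery
    on ground-truth fixtures."""
    rng = np.random.default_rng(seed)
    sens, false = [], []
    for _ in range(n_traces):
        trace, blink_mask, _ = make_pupil_fixture(
            seed=int(rng.integers(2**31)), n_trials=n_trials, n_blinks=5
        )
        mask = detect_artifacts(trace)
        s, f = detection_rates(mask, blink_mask)
        sens.append(s)
        false.append(f)
    trace, _, amplitudes = make_pupil_fixture(seed=int(rng.integers(2**31)),
                                              n_trials=100, n_blinks=12)
    _, table, _ = preprocess_trace(trace)
    ok = table.trials["valid"].to_numpy()
    r = float(np.corrcoef(amplitudes[ok], table.trials.loc[ok, "max_dilation"])[0, 1])
    return {
        "sensitivity": float(np.mean(sens)),
        "false_flag_rate": float(np.mean(false)),
        "amplitude_recovery_r": r,
        "n_traces": n_traces,
    }


# ---------------------------------------------------------------------------
# end-to-end planted-effect recovery

STRONG_EFFECT = dict(
    surprise_gain=0.10,
    entropy_gain=0.03,
    surprise_block_gain=0.0,
    surprise_trait_gain=0.0,
    surprise_block_trait_gain=0.30,
    entropy_block_trait_gain=0.0,
    entropy_trait_gain=0.0,
)

NULL_EFFECT = dict(
    surprise_gain=0.0,
    entropy_gain=0.0,
    surprise_block_gain=0.0,
    surprise_trait_gain=0.0,
    surprise_block_trait_gain=0.0,
    entropy_block_trait_gain=0.0,
    entropy_trait_gain=0.0,
)


def _run_study_lme(config: StudyConfig, term: str = "z_surprise:block:aq") -> tuple[float, float]:
    study = simulate_study(config)
    table = study_trial_table(study, use_fitted=True, n_starts=3, seed=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        et = lme_pupil_latent(
            table.rename(columns={"aq": "trait"}), latent="z_surprise", trait_name="aq"
        )
    return et.coef(term), et.pvalue(term)


def planted_effect_power(n_studies: int = 20, n_subjects: int = 52,
                         n_trials: int = 40, seed: int = 0) -> dict:
    """Detection rate of a strong planted surprise x block x trait pupil
    coupling across replicate synthetic studies (full pipeline: simulate ->
    fit -> latents -> pupil preprocessing -> mixed model)."""
    rng = np.random.default_rng(seed)
    hits = 0
    betas = []
    for _ in range(n_studies):
        cfg = StudyConfig(n_subjects=n_subjects, n_trials=n_trials,
                          seed=int(rng.integers(2**31)), **STRONG_EFFECT)
        beta, p = _run_study_lme(cfg)
        betas.append(beta)
        hits += int(beta > 0 and p < 0.05)
    return {
        "detection_rate": hits / n_studies,
        "mean_beta": float(np.mean(betas)),
        "n_studies": n_studies,
    }


def null_false_positive_rate(n_studies: int = 100, n_subjects: int = 24,
                             n_trials: int = 30, seed: int = 0) -> dict:
    """False-positive rate of the same interaction term on null studies
    (no latent-pupil coupling planted)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_studies):
        cfg = StudyConfig(n_subjects=n_subjects, n_trials=n_trials,
                          seed=int(rng.integers(2**31)), **NULL_EFFECT)
        _, p = _run_study_lme(cfg)
        hits += int(p < 0.05)
    return {"false_positive_rate": hits / n_studies, "n_studies": n_studies}


def schedule_battery(n_schedules: int = 1000, seed: int = 0) -> dict:
    """Structural checks over many seeded schedules."""
    rng = np.random.default_rng(seed)
    lengths = []
    all_ok = True
    for _ in range(n_schedules):
        vol = generate_schedule(160, 20, 4, seed=int(rng.integers(2**31)))
        cued = derive_cued_schedule(vol)
        lengths.extend(len(s) for s in vol.segments[:-1])  # last may be truncated
        ok = (
            all(16 <= len(s) <= 24 for s in vol.segments[:-1])
            and cued.change_trials == vol.change_trials
            and all(
                abs(sc.p_left - (1 - sv.p_left)) < 1e-9 and sc.risk_level == sv.risk_level
                for sv, sc in zip(vol.segments, cued.segments)
            )
        )
        all_ok = all_ok and ok
    return {
        "all_structural_checks_pass": all_ok,
        "mean_segment_length": float(np.mean(lengths)),
        "n_schedules": n_schedules,
    }
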