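"""Synthetic-study generator.

Produces complete synthetic cohorts for the two-block prediction task:
per-subject trait scores (AQ in [0, 1], CAPE-P in [1, 4], truncated-normal
marginals), per-block belief-model parameters linked to a trait through a
Gaussian copula at a configured rank correlation, simulated choice behavior,
and raw 500 Hz pupil traces in which the event-evoked response amplitude is
coupled to the trial-wise latents (entropy and Bayesian surprise) with
block- and trait-moderation terms — the generative structure the trial-level
pupil models are designed to detect. Blink artifacts and Gaussian noise are
added so the traces exercise the full preprocessing chain. Ground truth
(true parameters and planted effect sizes) is always written beside the
data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .latents import latent_table
from .models import BehaviorSession, HMMRPParams, filter_beliefs, simulate_agent
from .pupil import PupilTrace
from .task import RiskSchedule, derive_cued_schedule, generate_schedule, sample_outcomes, schedule_table

__all__ = [
    "SubjectProfile",
    "StudyConfig",
    "StudyData",
    "sample_subjects",
    "simulate_study_behavior",
    "simulate_pupil",
    "simulate_study",
    "generate_study",
]

BLOCKS = ("volatile", "cued")
_BLK_CODE = {"volatile": -0.5, "cued": 0.5}


@dataclass
class StudyConfig:
    """Generative conditions of one synthetic study.

    Defaults encode the emulated study: 52 subjects, two 160-trial blocks
    with 20 (+/-4)-trial segments, Table-1-like trait marginals, group-mean
    transition probabilities of 0.22 (volatile) and 0.10 (cued), and a
    positive trait-volatility rank correlation in the cued block.
    """

    n_subjects: int = 52
    n_trials: int = 160
    base_length: int = 20
    jitter: int = 4
    seed: int = 0

    # trait marginals (instrument bounds [0,1] and [1,4])
    aq_mean: float = 0.30
    aq_sd: float = 0.15
    cape_mean: float = 1.46
    cape_sd: float = 0.30
    aq_cape_rho: float = 0.25

    # belief-model parameter population
    gamma_mean_volatile: float = 0.22
    gamma_mean_cued: float = 0.10
    gamma_logit_sd: float = 0.5
    c_pos_mean: float = 0.80
    c_neg_mean: float = 0.72
    c_sd: float = 0.04
    inv_temp_log_mean: float = np.log(5.0)
    inv_temp_log_sd: float = 0.25

    # copula link between a trait and per-block gamma (rank correlations)
    gamma_trait: str = "cape_p"
    gamma_trait_rho_volatile: float = 0.16
    gamma_trait_rho_cued: float = 0.28

    # pupil response coupling (amplitudes in raw trace units)
    pupil_base_amp: float = 0.30
    entropy_gain: float = 0.04
    surprise_gain: float = 0.04
    entropy_block_gain: float = 0.0
    surprise_block_gain: float = -0.03
    entropy_trait_gain: float = 0.0  # moderated by CAPE-P
    surprise_trait_gain: float = -0.02  # moderated by AQ
    entropy_block_trait_gain: float = 0.04
    surprise_block_trait_gain: float = 0.05

    # raw trace structure
    trial_duration_ms: float = 4000.0
    outcome_onset_in_trial_ms: float = 1500.0
    sample_interval_ms: float = 2.0
    pupil_baseline: float = 5.0
    drift_amp: float = 0.10
    noise_sd: float = 0.05
    blink_rate_per_min: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for name in ("aq_cape_rho", "gamma_trait_rho_volatile", "gamma_trait_rho_cued"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.gamma_trait not in ("aq", "cape_p"):
            raise ValueError("gamma_trait must be 'aq' or 'cape_p'")


@dataclass
class SubjectProfile:
    """One subject's traits, model parameters, and pupil coupling."""

    participant: str
    aq: float
    cape_p: float
    params: dict[str, HMMRPParams]  # per block
    entropy_gain: dict[str, float]  # per block, raw trace units
    surprise_gain: dict[str, float]
    base_amp: float
    blink_rate_per_min: float
    noise_sd: float


@dataclass
class StudyData:
    """In-memory synthetic study: everything the pipeline consumes."""

    config: StudyConfig
    schedules: dict[str, RiskSchedule]
    profiles: list[SubjectProfile]
    sessions: dict[tuple[str, str], BehaviorSession]  # (participant, block)
    latents: pd.DataFrame  # true-parameter latents, z-scored per session
    traces: dict[tuple[str, str], PupilTrace]
    truth: dict

    def reset_trials(self, block: str):
        return self.schedules[block].change_trials if block == "cued" else None


def _spearman_to_pearson(rho: float) -> float:
    return float(2.0 * np.sin(np.pi * rho / 6.0))


def _trunc_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Quantile of a truncated normal whose *truncated* mean equals ``mean``
    (the location parameter is solved for, so configured trait means are the
    population means)."""
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = brentq(lambda m: trunc_mean(m) - mean, lo - 10 * sd, hi + 10 * sd, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def sample_subjects(config: StudyConfig, seed: int | None = None) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Trait marginals are truncated normals; the configured trait and the
    per-block transition probabilities share a Gaussian copula at the
    configured rank correlations. Pupil coupling gains are assembled from
    the planted effect sizes using the cohort-standardized trait scores.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    from scipy.stats import norm

    # correlated standard normals: aq, cape, gamma_vol, gamma_cued
    r_tr = _spearman_to_pearson(config.aq_cape_rho)
    z_aq = rng.standard_normal(n)
    z_cape = r_tr * z_aq + np.sqrt(1 - r_tr**2) * rng.standard_normal(n)
    z_link = z_cape if config.gamma_trait == "cape_p" else z_aq
    rv = _spearman_to_pearson(config.gamma_trait_rho_volatile)
    rc = _spearman_to_pearson(config.gamma_trait_rho_cued)
    z_gv = rv * z_link + np.sqrt(1 - rv**2) * rng.standard_normal(n)
    z_gc = rc * z_link + np.sqrt(1 - rc**2) * rng.standard_normal(n)

    aq = _trunc_ppf(norm.cdf(z_aq), config.aq_mean, config.aq_sd, 0.0, 1.0)
    cape = _trunc_ppf(norm.cdf(z_cape), config.cape_mean, config.cape_sd, 1.0, 4.0)
    gamma_v = expit(logit(config.gamma_mean_volatile) + config.gamma_logit_sd * z_gv)
    gamma_c = expit(logit(config.gamma_mean_cued) + config.gamma_logit_sd * z_gc)

    c_pos = np.clip(
        rng.normal(config.c_pos_mean, config.c_sd, n), 0.51, 0.99
    )
    c_neg = np.clip(rng.normal(config.c_neg_mean, config.c_sd, n), 0.51, 0.99)
    inv_temp = np.exp(rng.normal(config.inv_temp_log_mean, config.inv_temp_log_sd, n))

    # cohort-standardized traits drive the planted pupil moderation
    zs_aq = (aq - aq.mean()) / aq.std(ddof=1)
    zs_cape = (cape - cape.mean()) / cape.std(ddof=1)

    profiles = []
    for i in range(n):
        params = {
            "volatile": HMMRPParams(float(gamma_v[i]), float(c_pos[i]), float(c_neg[i]), float(inv_temp[i])),
            "cued": HMMRPParams(float(gamma_c[i]), float(c_pos[i]), float(c_neg[i]), float(inv_temp[i])),
        }
        e_gain, s_gain = {}, {}
        for block in BLOCKS:
            blk = _BLK_CODE[block]
            e_gain[block] = float(
                config.entropy_gain
                + config.entropy_block_gain * blk
                + config.entropy_trait_gain * zs_cape[i]
                + config.entropy_block_trait_gain * blk * zs_cape[i]
            )
            s_gain[block] = float(
                config.surprise_gain
                + config.surprise_block_gain * blk
                + config.surprise_trait_gain * zs_aq[i]
                + config.surprise_block_trait_gain * blk * zs_aq[i]
            )
        profiles.append(
            SubjectProfile(
                participant=f"S{i + 1:03d}",
                aq=float(aq[i]),
                cape_p=float(cape[i]),
                params=params,
                entropy_gain=e_gain,
                surprise_gain=s_gain,
                base_amp=config.pupil_base_amp,
                blink_rate_per_min=config.blink_rate_per_min,
                noise_sd=config.noise_sd,
            )
        )
    return profiles


def simulate_study_behavior(
    profiles: list[SubjectProfile],
    schedules: dict[str, RiskSchedule],
    seed: int = 0,
) -> dict[tuple[str, str], BehaviorSession]:
    """One session per subject x block from the subject's belief-model
    parameters; cued-block agents reset beliefs at announced changes."""
    rng = np.random.default_rng(seed)
    sessions = {}
    for profile in profiles:
        for block in BLOCKS:
            sched = schedules[block]
            outcome_seed = int(rng.integers(0, 2**31 - 1))
            agent_seed = int(rng.integers(0, 2**31 - 1))
            outcomes = sample_outcomes(sched, outcome_seed)
            resets = sched.change_trials if block == "cued" else None
            sessions[(profile.participant, block)] = simulate_agent(
                "hmm_rp",
                profile.params[block],
                sched,
                outcomes,
                seed=agent_seed,
                reset_trials=resets,
                participant=profile.participant,
            )
    return sessions


def _response_kernel(dt_ms: float, t_max: float = 930.0, shape: float = 10.1,
                     support_ms: float = 3000.0) -> np.ndarray:
    """Pupillometric impulse response (gamma family), peak-normalized."""
    t = np.arange(dt_ms, support_ms + dt_ms, dt_ms)
    h = (t / t_max) ** shape * np.exp(shape * (1.0 - t / t_max))
    return h / h.max()


def simulate_pupil(
    session: BehaviorSession,
    latents: pd.DataFrame,
    profile: SubjectProfile,
    seed: int = 0,
    config: StudyConfig | None = None,
) -> PupilTrace:
    """Generate a raw 500 Hz pupil trace for one session.

    Trace = slow drift + per-trial event responses time-locked to outcome
    onsets, with amplitude ``a0 + s_e * z_entropy + s_s * z_surprise``
    (gains per the subject's profile and block), plus Gaussian noise and
    Poisson blink artifacts.
    """
    cfg = config or StudyConfig()
    if len(latents) != session.n_trials:
        raise ValueError("latents not aligned to session trials")
    rng = np.random.default_rng(seed)
    dt = cfg.sample_interval_ms
    n_per_trial = int(round(cfg.trial_duration_ms / dt))
    n = session.n_trials * n_per_trial
    time_ms = np.arange(n) * dt
    onsets = (
        np.arange(session.n_trials) * cfg.trial_duration_ms + cfg.outcome_onset_in_trial_ms
    )
    block = session.block_label
    z_e = latents["z_entropy"].to_numpy()
    z_s = latents["z_surprise"].to_numpy()
    amp = (
        profile.base_amp
        + profile.entropy_gain[block] * z_e
        + profile.surprise_gain[block] * z_s
    )

    d = np.full(n, cfg.pupil_baseline)
    # slow baseline drift
    phase = rng.uniform(0, 2 * np.pi)
    d += cfg.drift_amp * np.sin(2 * np.pi * time_ms / 120_000.0 + phase)
    kernel = _response_kernel(dt)
    for k, onset in enumerate(onsets):
        i0 = int(round(onset / dt))
        i1 = min(i0 + len(kernel), n)
        d[i0:i1] += amp[k] * kernel[: i1 - i0]
    if cfg.noise_sd > 0:
        d += rng.normal(0.0, cfg.noise_sd, n)

    # blink artifacts: sharp collapse to 0, floor, fast recovery
    total_min = n * dt / 60_000.0
    n_blinks = rng.poisson(profile.blink_rate_per_min * total_min)
    collapse = int(round(8 / dt))
    recover = int(round(40 / dt))
    for _ in range(n_blinks):
        floor_len = int(round(rng.uniform(100, 200) / dt))
        start = int(rng.integers(0, max(1, n - (collapse + floor_len + recover))))
        pre_val = d[start]
        post_idx = min(start + collapse + floor_len + recover, n - 1)
        post_val = d[post_idx]
        d[start : start + collapse] = np.linspace(pre_val, 0.0, collapse, endpoint=False)
        d[start + collapse : start + collapse + floor_len] = 0.0
        r0 = start + collapse + floor_len
        d[r0 : r0 + recover] = np.linspace(0.0, post_val, recover, endpoint=False)[: max(0, n - r0)]
    return PupilTrace(
        time_ms=time_ms,
        diameter=d,
        block_label=block,
        onsets_ms=onsets,
        participant=session.participant,
    )


def simulate_study(config: StudyConfig) -> StudyData:
    """Generate a complete in-memory study under the configured conditions.

    Latents are computed from each subject's *true* parameters (the ones
    that generated behavior) and drive the planted pupil coupling.
    """
    rng = np.random.default_rng(config.seed)
    sched_seed = int(rng.integers(0, 2**31 - 1))
    behav_seed = int(rng.integers(0, 2**31 - 1))
    volatile = generate_schedule(
        config.n_trials, config.base_length, config.jitter, seed=sched_seed,
        block_label="volatile",
    )
    schedules = {"volatile": volatile, "cued": derive_cued_schedule(volatile)}
    profiles = sample_subjects(config)
    sessions = simulate_study_behavior(profiles, schedules, seed=behav_seed)

    latent_frames = []
    traces = {}
    for profile in profiles:
        for block in BLOCKS:
            session = sessions[(profile.participant, block)]
            resets = schedules[block].change_trials if block == "cued" else None
            traj = filter_beliefs(session, profile.params[block], resets)
            lt = latent_table(traj, profile.participant, block)
            latent_frames.append(lt)
            pupil_seed = int(rng.integers(0, 2**31 - 1))
            traces[(profile.participant, block)] = simulate_pupil(
                session, lt, profile, seed=pupil_seed, config=config
            )
    latents = pd.concat(latent_frames, ignore_index=True)
    truth = {
        "config": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in asdict(config).items()
        },
        "subjects": {
            p.participant: {
                "aq": p.aq,
                "cape_p": p.cape_p,
                "params": {b: asdict(p.params[b]) for b in BLOCKS},
                "entropy_gain": p.entropy_gain,
                "surprise_gain": p.surprise_gain,
            }
            for p in profiles
        },
    }
    return StudyData(
        config=config,
        schedules=schedules,
        profiles=profiles,
        sessions=sessions,
        latents=latents,
        traces=traces,
        truth=truth,
    )


def generate_study(config: StudyConfig, out_dir: str | Path) -> Path:
    """Write a complete synthetic study to ``out_dir`` as delimited text.

    Outputs: per-block schedule tables, the trial-level behavior table, the
    trait table, per-session pupil sample tables, and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)

    for block, sched in study.schedules.items():
        schedule_table(sched).to_csv(out / f"schedule_{block}.csv", index=False)

    rows = []
    for (participant, block), session in study.sessions.items():
        for t in range(session.n_trials):
            rows.append(
                {
                    "participant": participant,
                    "block": block,
                    "trial": t + 1,
                    "choice": session.choices[t],
                    "stimulus": session.outcomes[t],
                    "correct": bool(session.correct[t]),
                }
            )
    pd.DataFrame(rows).to_csv(out / "sessions.csv", index=False)

    pd.DataFrame(
        [{"participant": p.participant, "aq": p.aq, "cape_p": p.cape_p} for p in study.profiles]
    ).to_csv(out / "traits.csv", index=False)

    study.latents.to_csv(out / "latents_true.csv", index=False)

    for (participant, block), trace in study.traces.items():
        df = pd.DataFrame(
            {"time_ms": trace.time_ms, "pupil": trace.diameter}
        )
        df["block"] = block
        onset_set = set(np.round(trace.onsets_ms, 6))
        df["event"] = np.where(
            np.isin(np.round(trace.time_ms, 6), list(onset_set)), "outcome", ""
        )
        df.to_csv(out / f"pupil_{participant}_{block}.csv", index=False)

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)
    return out
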