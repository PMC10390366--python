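"""End-to-end assembly: fit models, derive latents, preprocess pupil data,
and build the trial-level table the statistical models consume."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import ModelFit, fit_mle
from .latents import latent_table
from .models import HMMRPParams, filter_beliefs
from .pupil import preprocess_trace
from .synth import BLOCKS, StudyData

__all__ = ["fit_study", "study_trial_table", "gamma_by_participant"]


def fit_study(
    study: StudyData,
    model: str = "hmm_rp",
    n_starts: int = 5,
    seed: int = 0,
    prior_sd: float | None = 1.5,
) -> dict[tuple[str, str], ModelFit]:
    """Per-subject x block weak-MAP fits for one study."""
    fits = {}
    for i, ((participant, block), session) in enumerate(sorted(study.sessions.items())):
        fits[(participant, block)] = fit_mle(
            model,
            session,
            n_starts=n_starts,
            seed=seed + i,
            reset_trials=study.reset_trials(block),
            prior_sd=prior_sd,
        )
    return fits


def gamma_by_participant(fits: dict, block: str) -> pd.Series:
    """Transition-probability estimates of one block, indexed by participant."""
    data = {
        participant: fit.params["gamma"]
        for (participant, blk), fit in fits.items()
        if blk == block and "gamma" in fit.params
    }
    return pd.Series(data).sort_index()


def study_trial_table(
    study: StudyData,
    fits: dict | None = None,
    use_fitted: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    velocity_k: float = 6.0,
) -> pd.DataFrame:
    """Trial-level analysis table: z-scored latents joined to QC-passing
    pupil readouts and trait scores.

    With ``use_fitted`` the latents come from per-subject fitted parameters
    (the real-data path); otherwise the generator's true parameters are
    used.
    """
    if use_fitted and fits is None:
        fits = fit_study(study, n_starts=n_starts, seed=seed)
    traits = {p.participant: (p.aq, p.cape_p) for p in study.profiles}
    frames = []
    for profile in study.profiles:
        for block in BLOCKS:
            key = (profile.participant, block)
            session = study.sessions[key]
            resets = study.reset_trials(block)
            if use_fitted:
                pr = fits[key].params
                params = HMMRPParams(pr["gamma"], pr["c_pos"], pr["c_neg"], pr["inv_temp"])
            else:
                params = profile.params[block]
            traj = filter_beliefs(session, params, resets)
            lt = latent_table(traj, profile.participant, block)
            _, epochs, _ = preprocess_trace(study.traces[key], velocity_k=velocity_k)
            lt = lt.merge(
                epochs.trials[["trial", "valid", "max_dilation", "sqrt_max_dilation"]],
                on="trial",
            )
            aq, cape = traits[profile.participant]
            lt["aq"] = aq
            lt["cape_p"] = cape
            frames.append(lt)
    return pd.concat(frames, ignore_index=True)
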