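"""Behavioral summaries and the trial-level statistical models.

Accuracy (frequency of predicting the current majority stimulus) and switch
rate (frequency of changing the prediction between consecutive trials) are
aggregated per risk condition within each block. Condition x trait effects
on these summaries — and latent x block x trait effects on the trial-wise
pupil readout — are estimated with linear mixed-effects models with nested
random intercepts (risk within block within participant for the summaries;
block within participant for the trial-level pupil models). Continuous
variables are z-scored and the two-level factors effect-coded (-0.5/+0.5) so
the reported coefficients are standardized; Wald tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import spearmanr

from .models import BehaviorSession
from .task import RiskSchedule, majority_stimulus

__all__ = [
    "EffectTable",
    "behavioral_summaries",
    "lme_condition_trait",
    "lme_pupil_latent",
    "trait_volatility_correlation",
]

BLOCK_CODE = {"volatile": -0.5, "cued": 0.5}
RISK_CODE = {"low": -0.5, "high": 0.5}


@dataclass
class EffectTable:
    """Standardized fixed-effect estimates of one mixed-effects model."""

    table: pd.DataFrame  # term, beta, t, p, ci_low, ci_high
    meta: dict

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def behavioral_summaries(session: BehaviorSession, schedule: RiskSchedule) -> pd.DataFrame:
    """Accuracy and switch rate per risk condition for one session.

    Accuracy is the fraction of trials where the choice equals the current
    majority stimulus. A switch is a change of prediction from trial t to
    t+1 and is assigned to the risk condition of the destination trial t+1.
    """
    if session.n_trials != schedule.n_trials:
        raise ValueError("session and schedule lengths differ")
    risk = schedule.risk_per_trial()
    majority = np.array([majority_stimulus(schedule, t) for t in range(1, schedule.n_trials + 1)])
    hit = session.choices == majority
    switched = session.choices[1:] != session.choices[:-1]
    rows = []
    for level in ("low", "high"):
        sel = risk == level
        sel_dest = risk[1:] == level  # risk of trial t+1
        rows.append(
            {
                "participant": session.participant,
                "block": session.block_label,
                "risk_level": level,
                "accuracy": float(hit[sel].mean()) if sel.any() else np.nan,
                "switch_rate": float(switched[sel_dest].mean()) if sel_dest.any() else np.nan,
                "n_trials": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


def _effects_frame(result, terms) -> pd.DataFrame:
    ci = result.conf_int()
    rows = []
    for term in terms:
        rows.append(
            {
                "term": term,
                "beta": float(result.fe_params[term]),
                "t": float(result.tvalues[term]),
                "p": float(result.pvalues[term]),
                "ci_low": float(ci.loc[term, 0]),
                "ci_high": float(ci.loc[term, 1]),
            }
        )
    return pd.DataFrame(rows)


def _fit_mixedlm(formula, data, vc_formula, re_formula="1", groups="participant"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[groups], re_formula=re_formula, vc_formula=vc_formula
        )
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
    return result


def lme_condition_trait(
    summaries: pd.DataFrame,
    traits: pd.Series | dict,
    dv: str = "accuracy",
    trait_name: str = "trait",
) -> EffectTable:
    """Mixed model of a behavioral summary on block, risk, and a trait.

    Fixed effects: block, risk, trait, and all interactions up to
    block x risk x trait; random intercepts for participant, block within
    participant, and risk within block within participant.
    """
    if dv not in ("accuracy", "switch_rate"):
        raise ValueError("dv must be 'accuracy' or 'switch_rate'")
    df = summaries.copy()
    traits = pd.Series(traits)
    missing = set(df["participant"]) - set(traits.index)
    if missing:
        raise ValueError(f"trait score missing for participants {sorted(missing)}")
    df["trait"] = _zscore(traits.loc[df["participant"]].to_numpy())
    df["y"] = _zscore(df[dv].to_numpy())
    df["block_c"] = df["block"].map(BLOCK_CODE)
    df["risk_c"] = df["risk_level"].map(RISK_CODE)
    df["block_lbl"] = df["block"]
    df["cell_lbl"] = df["block"].astype(str) + ":" + df["risk_level"].astype(str)
    vc = {"block": "0 + C(block_lbl)", "risk_in_block": "0 + C(cell_lbl)"}
    formula = "y ~ block_c * risk_c * trait"
    try:
        result = _fit_mixedlm(formula, df, vc)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"rank-deficient or singular design: {err}") from err
    terms = [t for t in result.fe_params.index if t != "Intercept"]
    table = _effects_frame(result, terms)
    table["term"] = table["term"].str.replace("block_c", "block").str.replace(
        "risk_c", "risk"
    ).str.replace("trait", trait_name)
    return EffectTable(
        table=table,
        meta={
            "dv": dv,
            "trait": trait_name,
            "n_obs": int(len(df)),
            "n_participants": int(df["participant"].nunique()),
            "random_effects": "participant + block-in-participant + risk-in-block-in-participant",
            "converged": bool(result.converged),
        },
    )


def lme_pupil_latent(
    trials: pd.DataFrame,
    latent: str = "z_surprise",
    trait_name: str = "trait",
    dv: str = "sqrt_max_dilation",
    random_slopes: bool = True,
) -> EffectTable:
    """Trial-level mixed model of pupil dilation on a z-scored latent.

    Expects one row per QC-passing trial with columns ``participant``,
    ``block``, the latent column (z-scored per participant x block), ``dv``,
    and a ``trait`` column. Fixed effects are latent, block, trait and all
    interactions; random intercepts for participant and block within
    participant, plus (by default) per-participant random slopes for the
    latent and its block interaction. The slopes matter for calibration:
    trial-level pupil readouts are temporally autocorrelated, and with
    intercept-only random effects the trait-moderated slope terms are tested
    against an SE that ignores between-subject slope variability, inflating
    false positives.
    """
    required = {"participant", "block", latent, dv, "trait"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials table missing columns {required - set(trials.columns)}")
    df = trials.copy()
    cells_before = set(map(tuple, df[["participant", "block"]].drop_duplicates().to_numpy()))
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df.dropna(subset=[latent, dv, "trait"])
    cells_after = set(map(tuple, df[["participant", "block"]].drop_duplicates().to_numpy()))
    dropped = cells_before - cells_after
    if dropped:
        warnings.warn(f"no valid trials; dropping participant x block cells: {sorted(dropped)}")
    df = df.copy()
    df["y"] = _zscore(df[dv].to_numpy())
    df["x"] = df[latent].to_numpy()
    df["trait_z"] = _zscore(df["trait"].to_numpy())
    df["block_c"] = df["block"].map(BLOCK_CODE)
    df["block_lbl"] = df["block"]
    vc = {"block": "0 + C(block_lbl)"}
    re_formula = "1 + x + x:block_c" if random_slopes else "1"
    result = _fit_mixedlm("y ~ x * block_c * trait_z", df, vc, re_formula=re_formula)
    terms = [t for t in result.fe_params.index if t != "Intercept"]
    table = _effects_frame(result, terms)
    table["term"] = (
        table["term"]
        .str.replace("x", latent)
        .str.replace("block_c", "block")
        .str.replace("trait_z", trait_name)
    )
    return EffectTable(
        table=table,
        meta={
            "dv": dv,
            "latent": latent,
            "trait": trait_name,
            "n_obs": int(len(df)),
            "n_participants": int(df["participant"].nunique()),
            "random_effects": (
                "participant + block-in-participant"
                + (" + latent, latent:block slopes" if random_slopes else "")
            ),
            "converged": bool(result.converged),
        },
    )


def trait_volatility_correlation(traits, gamma_estimates) -> tuple[float, float]:
    """Spearman rank correlation between a trait score and per-participant
    transition-probability estimates (two-sided p)."""
    x = np.asarray(traits, dtype=float)
    y = np.asarray(gamma_estimates, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = spearmanr(x[ok], y[ok])
    return float(rho), float(p)
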