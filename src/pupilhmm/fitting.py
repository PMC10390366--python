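"""Model fitting, comparison, and posterior block contrasts.

Each candidate model is fitted per participant x block to the observed
choice sequence by maximizing the summed log choice probability over
bounded, transformed parameters (logit for probabilities, a scaled logit for
emission strengths in (0.5, 1), log for the inverse temperature). A
hierarchical Bayesian layer places Gaussian population distributions over
the transformed per-subject parameters and samples the joint posterior with
affine-invariant ensemble MCMC; convergence is monitored with split R-hat
and posterior draws of the transition probability are retained so the two
task blocks can be contrasted via the highest-density interval of their
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .models import (
    MODEL_NAMES,
    MODEL_PARAM_NAMES,
    BehaviorSession,
    HMMRPParams,
    RLParams,
    WSLSParams,
    _hmm_loglik_core,
    _resets_array,
    _rl_loglik_core,
    _wsls_loglik_core,
)

__all__ = [
    "ModelFit",
    "ModelComparison",
    "HierarchicalFit",
    "session_log_likelihood",
    "fit_mle",
    "fit_hierarchical",
    "compare_models",
    "posterior_block_contrast",
]

LIKELIHOOD_FLOOR = 1e-12

_RL_CODES = {"rescorla_wagner": 0, "dual_rate": 1, "pearce_hall": 2, "double_update": 3}


@dataclass
class ModelFit:
    """Fitted parameters and fit statistics for one participant x block."""

    model: str
    participant: str
    block_label: str
    params: dict[str, float]
    log_likelihood: float
    n_params: int
    n_trials: int
    n_starts: int = 0
    converged: bool = True
    posterior: dict | None = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2 * self.log_likelihood


@dataclass
class ModelComparison:
    """Summed-criterion ranking of models over a cohort."""

    criterion: str
    table: pd.DataFrame  # model, total, rank, n_best
    best_model: str


@dataclass
class HierarchicalFit:
    """Per-subject posterior fits plus group-level summaries."""

    model: str
    fits: list[ModelFit]
    group: dict
    rhat: dict[str, float]
    converged: bool
    gamma_draws: np.ndarray | None = None  # group-level, natural scale
    subject_gamma_draws: np.ndarray | None = None  # (n_subjects, n_draws)


# ---------------------------------------------------------------------------
# parameter transforms


def _to_natural(x: np.ndarray, kinds) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    eps = 1e-9  # keep probabilities strictly interior so the filter stays finite
    for i, kind in enumerate(kinds):
        if kind == "u":
            out[i] = np.clip(expit(x[i]), eps, 1 - eps)
        elif kind == "h":
            out[i] = np.clip(0.5 + 0.5 * expit(x[i]), 0.5 + eps, 1 - eps)
        else:  # "p": log scale, clipped to keep exp finite
            out[i] = np.exp(np.clip(x[i], -8.0, 6.0))
    return out


def _to_unconstrained(p: np.ndarray, kinds) -> np.ndarray:
    out = np.empty_like(p, dtype=float)
    for i, kind in enumerate(kinds):
        if kind == "u":
            out[i] = logit(np.clip(p[i], 1e-9, 1 - 1e-9))
        elif kind == "h":
            out[i] = logit(np.clip((p[i] - 0.5) * 2.0, 1e-9, 1 - 1e-9))
        else:
            out[i] = np.log(p[i])
    return out


def _param_kinds(model: str):
    return [kind for _, kind in MODEL_PARAM_NAMES[model]]


def _param_names(model: str):
    return [name for name, _ in MODEL_PARAM_NAMES[model]]


def _params_to_array(model: str, params) -> np.ndarray:
    names = _param_names(model)
    if isinstance(params, dict):
        return np.array([float(params[n]) for n in names])
    if isinstance(params, HMMRPParams):
        if model == "hmm_rp":
            return np.array([params.gamma, params.c_pos, params.c_neg, params.inv_temp])
        if model == "hmm":
            if params.c_pos != params.c_neg:
                raise ValueError("single-c model requires c_pos == c_neg")
            return np.array([params.gamma, params.c_pos, params.inv_temp])
    if isinstance(params, WSLSParams) and model == "wsls":
        return np.array([params.p_stay_win, params.p_shift_lose])
    if isinstance(params, RLParams) and model in _RL_CODES:
        if params.variant != model:
            raise ValueError(f"params for {params.variant!r} passed to model {model!r}")
        vals = [getattr(params, n) for n in names[:-1]] + [params.inv_temp]
        return np.array(vals, dtype=float)
    if isinstance(params, (list, tuple, np.ndarray)):
        arr = np.asarray(params, dtype=float)
        if arr.shape != (len(names),):
            raise ValueError(f"{model} expects {len(names)} parameters")
        return arr
    raise TypeError(f"cannot interpret parameters of type {type(params)!r} for {model}")


def _loglik_theta(
    model: str,
    theta: np.ndarray,
    choices_left: np.ndarray,
    outcomes_left: np.ndarray,
    resets: np.ndarray,
    floor: float = LIKELIHOOD_FLOOR,
) -> float:
    if model == "hmm_rp":
        return _hmm_loglik_core(
            choices_left, outcomes_left, resets, theta[0], theta[1], theta[2], theta[3], floor
        )
    if model == "hmm":
        return _hmm_loglik_core(
            choices_left, outcomes_left, resets, theta[0], theta[1], theta[1], theta[2], floor
        )
    if model == "wsls":
        return _wsls_loglik_core(choices_left, outcomes_left, theta[0], theta[1], floor)
    code = _RL_CODES[model]
    p2 = theta[1] if len(theta) == 3 else 0.0
    return _rl_loglik_core(choices_left, outcomes_left, code, theta[0], p2, theta[-1], floor)


def session_log_likelihood(
    model: str,
    params,
    session: BehaviorSession,
    reset_trials=None,
    floor: float = LIKELIHOOD_FLOOR,
) -> float:
    """Summed log probability of the observed choices under ``model``.

    The model's internal state is driven by the observed choices and
    outcomes; trial 1 contributes ln 0.5 under the symmetric initialization.
    Choice probabilities of exactly zero are clamped at ``floor``.
    """
    if model not in MODEL_NAMES:
        raise KeyError(f"unknown model {model!r}")
    theta = _params_to_array(model, params)
    resets = _resets_array(session.n_trials, reset_trials)
    return float(
        _loglik_theta(model, theta, session.choices_left(), session.outcomes_left(), resets, floor)
    )


# ---------------------------------------------------------------------------
# per-subject maximum likelihood


def fit_mle(
    model: str,
    session: BehaviorSession,
    n_starts: int = 10,
    seed: int = 0,
    reset_trials=None,
    floor: float = LIKELIHOOD_FLOOR,
    prior_sd: float | None = 1.5,
) -> ModelFit:
    """Per-session point fit of one model (regularized maximum likelihood).

    Optimizes on unconstrained scales from ``n_starts`` seeded jittered
    initializations and keeps the best optimum. By default a weakly
    informative Gaussian ridge ``N(0, prior_sd)`` on the unconstrained
    parameters makes this a MAP estimate: single sessions leave a scaling
    ridge between the emission strength and the inverse temperature nearly
    unidentified, and unregularized ML drifts to degenerate boundary optima
    (``c -> 0.5`` with runaway ``inv_temp``) whose belief trajectories are
    uninterpretable. ``prior_sd=None`` gives the pure maximum-likelihood
    fit. The reported ``log_likelihood`` is always the data log likelihood
    at the optimum (the prior is never included in AIC/BIC).
    """
    if model not in MODEL_NAMES:
        raise KeyError(f"unknown model {model!r}")
    if session.n_trials < 20:
        raise ValueError("session too short to fit (need >= 20 trials)")
    kinds = _param_kinds(model)
    names = _param_names(model)
    dim = len(kinds)
    choices_left = session.choices_left()
    outcomes_left = session.outcomes_left()
    resets = _resets_array(session.n_trials, reset_trials)

    def objective(x):
        x = np.asarray(x)
        theta = _to_natural(x, kinds)
        nll = -_loglik_theta(model, theta, choices_left, outcomes_left, resets, floor)
        if prior_sd is not None:
            nll += 0.5 * float(np.sum((x / prior_sd) ** 2))
        return nll

    rng = np.random.default_rng(seed)
    best_x, best_nll, any_ok = None, np.inf, False
    for start in range(n_starts):
        x0 = np.zeros(dim) if start == 0 else rng.normal(0.0, 1.5, dim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(objective, x0, method="L-BFGS-B")
        if np.isfinite(res.fun):
            any_ok = any_ok or bool(res.success)
            if res.fun < best_nll:
                best_nll, best_x = res.fun, res.x
    if best_x is None:
        raise RuntimeError(f"all {n_starts} starts failed for model {model}")
    theta = _to_natural(best_x, kinds)
    data_ll = float(_loglik_theta(model, theta, choices_left, outcomes_left, resets, floor))
    return ModelFit(
        model=model,
        participant=session.participant,
        block_label=session.block_label,
        params=dict(zip(names, map(float, theta))),
        log_likelihood=data_ll,
        n_params=dim,
        n_trials=session.n_trials,
        n_starts=n_starts,
        converged=any_ok,
    )


# ---------------------------------------------------------------------------
# hierarchical Bayesian layer (ensemble MCMC)


def fit_hierarchical(
    model: str,
    sessions: list[BehaviorSession],
    reset_trials=None,
    n_steps: int = 1500,
    n_burn: int = 500,
    n_walkers: int | None = None,
    seed: int = 0,
    rhat_threshold: float = 1.01,
) -> HierarchicalFit:
    """Sample the joint posterior of a hierarchical model over sessions.

    Transformed per-subject parameters are drawn from Gaussian population
    distributions (non-centered parameterization); hyperpriors are
    ``mu ~ N(0, 2)`` and ``sigma ~ HalfNormal(1)``. The sampler is an
    affine-invariant ensemble; R-hat is computed per parameter by treating
    walkers as chains and the fit is flagged unconverged if any exceeds
    ``rhat_threshold``.
    """
    import emcee

    if model not in MODEL_NAMES:
        raise KeyError(f"unknown model {model!r}")
    if len(sessions) < 5:
        raise ValueError("hierarchical fit requires at least 5 sessions")
    kinds = _param_kinds(model)
    names = _param_names(model)
    n_par = len(kinds)
    n_sub = len(sessions)
    dim = 2 * n_par + n_sub * n_par

    data = []
    for i, s in enumerate(sessions):
        rt = None if reset_trials is None else reset_trials[i]
        data.append((s.choices_left(), s.outcomes_left(), _resets_array(s.n_trials, rt)))

    def log_prob(x):
        mu = x[:n_par]
        log_sigma = x[n_par : 2 * n_par]
        if np.any(np.abs(log_sigma) > 5) or np.any(np.abs(mu) > 20):
            return -np.inf
        sigma = np.exp(log_sigma)
        z = x[2 * n_par :].reshape(n_sub, n_par)
        lp = -0.5 * np.sum((mu / 2.0) ** 2)
        lp += np.sum(-0.5 * sigma**2 + log_sigma)  # HalfNormal(1) + Jacobian
        lp += -0.5 * np.sum(z**2)
        subj = mu[None, :] + sigma[None, :] * z
        for i in range(n_sub):
            theta = _to_natural(subj[i], kinds)
            lp += _loglik_theta(model, theta, *data[i])
        return lp if np.isfinite(lp) else -np.inf

    if n_walkers is None:
        n_walkers = max(2 * dim + 2, 24)
    rng = np.random.default_rng(seed)
    p0 = rng.normal(0.0, 0.1, size=(n_walkers, dim))
    sampler = emcee.EnsembleSampler(n_walkers, dim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn)  # (draws, walkers, dim)
    draws = np.moveaxis(chain, 0, 1)  # (walkers, draws, dim)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_vals = {}
        for j in range(2 * n_par):
            name = (f"mu_{names[j]}" if j < n_par else f"sigma_{names[j - n_par]}")
            rhat_vals[name] = float(az.rhat(draws[:, :, j]))
    converged = all(np.isfinite(v) and v < rhat_threshold for v in rhat_vals.values())

    flat = draws.reshape(-1, dim)
    mu_draws = flat[:, :n_par]
    sigma_draws = np.exp(flat[:, n_par : 2 * n_par])
    # natural-scale draws
    group_nat = np.column_stack(
        [_to_natural_vec(mu_draws[:, j], kinds[j]) for j in range(n_par)]
    )
    subj_nat = np.empty((n_sub, flat.shape[0], n_par))
    for i in range(n_sub):
        block = flat[:, 2 * n_par + i * n_par : 2 * n_par + (i + 1) * n_par]
        x_sub = mu_draws + sigma_draws * block
        for j in range(n_par):
            subj_nat[i, :, j] = _to_natural_vec(x_sub[:, j], kinds[j])

    fits = []
    for i, s in enumerate(sessions):
        post = {}
        point = {}
        for j, name in enumerate(names):
            d = subj_nat[i, :, j]
            hdi = az.hdi(d, hdi_prob=0.95)
            post[name] = {
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "hdi_2.5%": float(hdi[0]),
                "hdi_97.5%": float(hdi[1]),
            }
            point[name] = float(d.mean())
        theta = np.array([point[n] for n in names])
        rt = None if reset_trials is None else reset_trials[i]
        ll = _loglik_theta(model, theta, *data[i])
        fits.append(
            ModelFit(
                model=model,
                participant=s.participant,
                block_label=s.block_label,
                params=point,
                log_likelihood=float(ll),
                n_params=n_par,
                n_trials=s.n_trials,
                converged=converged,
                posterior=post,
            )
        )

    group = {
        "mu_mean": dict(zip(names, map(float, mu_draws.mean(axis=0)))),
        "sigma_mean": dict(zip(names, map(float, sigma_draws.mean(axis=0)))),
        "natural_mean": dict(zip(names, map(float, group_nat.mean(axis=0)))),
    }
    gamma_draws = subject_gamma = None
    if "gamma" in names:
        j = names.index("gamma")
        gamma_draws = group_nat[:, j]
        subject_gamma = subj_nat[:, :, j]
    if not converged:
        warnings.warn(
            f"hierarchical fit of {model} not converged "
            f"(max R-hat {max(rhat_vals.values()):.3f})",
            RuntimeWarning,
        )
    return HierarchicalFit(
        model=model,
        fits=fits,
        group=group,
        rhat=rhat_vals,
        converged=converged,
        gamma_draws=gamma_draws,
        subject_gamma_draws=subject_gamma,
    )


def _to_natural_vec(x: np.ndarray, kind: str) -> np.ndarray:
    eps = 1e-9
    if kind == "u":
        return np.clip(expit(x), eps, 1 - eps)
    if kind == "h":
        return np.clip(0.5 + 0.5 * expit(x), 0.5 + eps, 1 - eps)
    return np.exp(np.clip(x, -8.0, 6.0))


# ---------------------------------------------------------------------------
# model comparison and posterior contrasts


def compare_models(fits_by_model: dict[str, list[ModelFit]], criterion: str = "bic") -> ModelComparison:
    """Rank models by summed information criterion over the cohort.

    Requires identical participant x block coverage per model; ties are
    broken by model-id (alphabetical) order.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    coverage = None
    for model, fits in fits_by_model.items():
        keys = sorted((f.participant, f.block_label) for f in fits)
        if coverage is None:
            coverage = keys
        elif keys != coverage:
            raise ValueError(f"subject x block coverage of {model} differs from other models")
    totals = {
        m: sum(getattr(f, criterion) for f in fits) for m, fits in fits_by_model.items()
    }
    order = sorted(totals, key=lambda m: (totals[m], m))
    n_best = {m: 0 for m in fits_by_model}
    by_key: dict[tuple, list[tuple[float, str]]] = {}
    for m, fits in fits_by_model.items():
        for f in fits:
            by_key.setdefault((f.participant, f.block_label), []).append(
                (getattr(f, criterion), m)
            )
    for vals in by_key.values():
        n_best[min(vals)[1]] += 1
    table = pd.DataFrame(
        {
            "model": order,
            "total": [totals[m] for m in order],
            "rank": np.arange(1, len(order) + 1),
            "n_best": [n_best[m] for m in order],
        }
    )
    return ModelComparison(criterion=criterion, table=table, best_model=order[0])


def posterior_block_contrast(
    gamma_draws_volatile: np.ndarray,
    gamma_draws_cued: np.ndarray,
    credibility: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mean difference and HDI of paired posterior draws (volatile - cued).

    Unequal draw counts are reconciled by seeded resampling of the shorter
    set.
    """
    a = np.asarray(gamma_draws_volatile, dtype=float)
    b = np.asarray(gamma_draws_cued, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty posterior draws")
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        n = max(a.size, b.size)
        if a.size < n:
            a = rng.choice(a, size=n, replace=True)
        else:
            b = rng.choice(b, size=n, replace=True)
    diff = a - b
    hdi = az.hdi(diff, hdi_prob=credibility)
    return float(diff.mean()), (float(hdi[0]), float(hdi[1]))
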