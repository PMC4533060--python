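"""Parametric decision models of gamble acceptance and their ML fitting.

Three nested logistic choice models are fit to trial-by-trial accept/reject
decisions about 50/50 gambles (safe option always worth zero):

* model 1 — a single gamble-bias parameter ``g``:
  ``P(gamble) = 1 / (1 + exp(-g))``.
* model 2 — utility sensitivity:  ``U = 0.5*V_gain + 0.5*V_loss`` (the
  gamble expected value) and ``P(gamble) = 1 / (1 + exp(-mu*(U + g)))``.
* model 3 — adds loss aversion ``lam``:
  ``U = 0.5*V_gain + 0.5*lam*V_loss``; choice rule as in model 2.

``lam > 1`` means losses loom larger than equivalent gains.  Utilities are
in euro cents, so ``mu`` carries units of 1/cent and, for models 2/3, ``g``
is in cents (it sits inside the ``mu`` product).  Models are compared by
BIC; goodness of fit is McFadden's pseudo-r^2 against the chance
(P = 0.5 per trial) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "DecisionParams",
    "ModelFit",
    "utility",
    "prob_gamble",
    "simulate_choices",
    "fit_model",
    "compare_models",
    "ev_choice_resampling_test",
    "N_FREE_PARAMS",
]

N_FREE_PARAMS = {1: 1, 2: 2, 3: 3}

# deterministic multi-start restart grid and box bounds
_G_STARTS = (-2.0, 0.0, 2.0)
_MU_STARTS = (0.01, 0.1, 1.0)
_LAM_STARTS = (0.5, 1.0, 2.0, 4.0)
_G_BOUNDS = (-100.0, 100.0)
_MU_BOUNDS = (1e-6, 10.0)
_LAM_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class DecisionParams:
    """Parameters of the choice models; unused fields default to neutral."""

    g: float = 0.0
    mu: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")


@dataclass
class ModelFit:
    model_id: int
    params: DecisionParams
    loglik: float
    bic: float
    pseudo_r2: float
    n_trials: int
    boundary: bool = False
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": {"g": self.params.g, "mu": self.params.mu, "lam": self.params.lam},
            "loglik": self.loglik,
            "bic": self.bic,
            "pseudo_r2": self.pseudo_r2,
            "n_trials": self.n_trials,
        }


def utility(offer, lam: float) -> float:
    """Subjective gamble utility ``0.5*gain + 0.5*lam*loss`` (euro cents)."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return 0.5 * offer.gain + 0.5 * lam * offer.loss


def _utilities(gains: np.ndarray, losses: np.ndarray, lam: float) -> np.ndarray:
    return 0.5 * gains + 0.5 * lam * losses


def prob_gamble(model_id: int, offer, params: DecisionParams) -> float:
    """Probability of accepting the gamble under the given model."""
    if model_id == 1:
        return float(expit(params.g))
    if model_id in (2, 3):
        lam = params.lam if model_id == 3 else 1.0
        u = utility(offer, lam)
        return float(expit(params.mu * (u + params.g)))
    raise ValueError(f"unknown model_id {model_id}")


def _prob_gamble_vec(model_id, gains, losses, g, mu, lam) -> np.ndarray:
    if model_id == 1:
        return np.full(len(gains), expit(g))
    lam_eff = lam if model_id == 3 else 1.0
    return expit(mu * (_utilities(gains, losses, lam_eff) + g))


def simulate_choices(
    design: pd.DataFrame,
    model_id: int,
    params: DecisionParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate accept/reject choices and fair-coin gamble outcomes.

    Returns the design table with ``chose_gamble`` (0/1) and
    ``outcome_cents`` (NaN on safe-choice trials) columns appended.
    """
    rng = np.random.default_rng(seed)
    gains = design["gain_cents"].to_numpy(float)
    losses = design["loss_cents"].to_numpy(float)
    p = _prob_gamble_vec(model_id, gains, losses, params.g, params.mu, params.lam)
    chose = rng.random(len(design)) < p
    won = rng.random(len(design)) < 0.5
    outcome = np.where(won, gains, losses)
    outcome = np.where(chose, outcome, np.nan)
    trials = design.copy()
    trials["chose_gamble"] = chose.astype(int)
    trials["outcome_cents"] = outcome
    return trials


def _neg_loglik_and_grad(theta, model_id, gains, losses, y):
    """Negative Bernoulli log-likelihood and its analytic gradient."""
    if model_id == 1:
        z = np.full(len(y), theta[0])
    else:
        g, mu = theta[0], theta[1]
        lam = theta[2] if model_id == 3 else 1.0
        u = _utilities(gains, losses, lam)
        z = mu * (u + g)
    p = expit(z)
    # clip away exact 0/1 so the log is finite at the box bounds
    p = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    resid = p - y  # d(nll)/dz
    if model_id == 1:
        grad = np.array([resid.sum()])
    else:
        g, mu = theta[0], theta[1]
        lam = theta[2] if model_id == 3 else 1.0
        u = _utilities(gains, losses, lam)
        dg = mu * resid.sum()
        dmu = np.sum(resid * (u + g))
        if model_id == 3:
            dlam = np.sum(resid * mu * 0.5 * losses)
            grad = np.array([dg, dmu, dlam])
        else:
            grad = np.array([dg, dmu])
    return nll, grad


def fit_model(trials: pd.DataFrame, model_id: int) -> ModelFit:
    """Maximum-likelihood fit of one choice model to a trial table.

    Uses L-BFGS-B from a deterministic grid of restarts; the best
    (highest-likelihood) solution is kept.  All-one-choice data produce a
    boundary fit that is flagged rather than rejected.
    """
    if model_id not in N_FREE_PARAMS:
        raise ValueError(f"unknown model_id {model_id}")
    gains = trials["gain_cents"].to_numpy(float)
    losses = trials["loss_cents"].to_numpy(float)
    y = trials["chose_gamble"].to_numpy(float)
    n = len(y)
    warns: list[str] = []
    if n < 10 or y.min() == y.max():
        warns.append("degenerate data: fewer than 10 trials or a single choice type")

    if model_id == 1:
        starts = [(g,) for g in _G_STARTS]
        bounds = [_G_BOUNDS]
    elif model_id == 2:
        starts = [(g, mu) for g in _G_STARTS for mu in _MU_STARTS]
        bounds = [_G_BOUNDS, _MU_BOUNDS]
    else:
        starts = [
            (g, mu, lam) for g in _G_STARTS for mu in _MU_STARTS for lam in _LAM_STARTS
        ]
        bounds = [_G_BOUNDS, _MU_BOUNDS, _LAM_BOUNDS]

    best = None
    for x0 in starts:
        res = minimize(
            _neg_loglik_and_grad,
            np.asarray(x0, float),
            args=(model_id, gains, losses, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    at_bound = any(
        np.isclose(t, b[0]) or np.isclose(t, b[1]) for t, b in zip(theta, bounds)
    )
    if at_bound:
        warns.append("parameter at box bound")
    for w in warns:
        warnings.warn(w, stacklevel=2)

    if model_id == 1:
        params = DecisionParams(g=theta[0])
    elif model_id == 2:
        params = DecisionParams(g=theta[0], mu=theta[1])
    else:
        params = DecisionParams(g=theta[0], mu=theta[1], lam=theta[2])

    loglik = -best.fun
    k = N_FREE_PARAMS[model_id]
    bic = k * np.log(n) - 2.0 * loglik
    pseudo_r2 = 1.0 - loglik / (n * np.log(0.5))
    return ModelFit(
        model_id=model_id,
        params=params,
        loglik=float(loglik),
        bic=float(bic),
        pseudo_r2=float(pseudo_r2),
        n_trials=n,
        boundary=at_bound,
        warnings=warns,
    )


def fit_model1_closed_form(trials: pd.DataFrame) -> float:
    """Closed-form model-1 MLE: logit of the empirical gamble fraction."""
    frac = trials["chose_gamble"].to_numpy(float).mean()
    return float(logit(frac))


def compare_models(fits: list[ModelFit]) -> int:
    """Return the model_id with the lowest BIC; ties go to the simpler model."""
    ns = {f.n_trials for f in fits}
    if len(ns) != 1:
        raise ValueError("model fits are not on identical trial data (n differs)")
    ordered = sorted(fits, key=lambda f: (f.bic, f.model_id))
    return ordered[0].model_id


def ev_choice_resampling_test(
    trials: pd.DataFrame, n_resamples: int = 1000, seed: int = 0
) -> float:
    """One-sided shuffle test for an expected-value effect on choice.

    Statistic: P(gamble | EV>0) - P(gamble | EV<0), zero-EV trials
    excluded.  Choices are shuffled across trials; the p-value is the
    fraction of shuffles whose statistic is >= the observed one.
    """
    ev = trials["ev_cents"].to_numpy(float)
    y = trials["chose_gamble"].to_numpy(float)
    pos = ev > 0
    neg = ev < 0
    if not pos.any() or not neg.any():
        raise ValueError("design must contain both positive- and negative-EV offers")
    observed = y[pos].mean() - y[neg].mean()

    rng = np.random.default_rng(seed)
    keep = pos | neg
    y_k = y[keep]
    pos_k = pos[keep]
    n_k = len(y_k)
    # vectorized shuffles: each row is a permutation of the choice labels
    idx = np.argsort(rng.random((n_resamples, n_k)), axis=1)
    shuffled = y_k[idx]
    stat = shuffled[:, pos_k].mean(axis=1) - shuffled[:, ~pos_k].mean(axis=1)
    return float(np.mean(stat >= observed))
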