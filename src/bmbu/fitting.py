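"""Maximum-likelihood estimation of the observer parameters.

The likelihood of a choice sequence factorises over trials because boundary
retrievals are drawn fresh every trial: ``p(D(t) | Theta)`` has the
closed form implemented in :func:`bmbu.observer.choice_probability`.  Fitting
follows a three-stage multistart schedule: many short bounded simplex
searches from random initial points, refinement of the best candidates at
tight tolerance, and one repeat of the refinement stage.

The constant-boundary control model (fixed boundary ``mu0``, measurement sd
``sigma_m``) is fitted the same way with two parameters.  Model comparison
uses AIC and the Nagelkerke pseudo-R^2 against an intercept-only null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .observer import ObserverParams, _choice_probability_padded, constant_boundary_probability
from .trials import prepare_design

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "neg_log_likelihood",
    "neg_log_likelihood_constant",
    "fit_bmbu",
    "fit_constant",
    "compare_models",
    "nagelkerke_r2",
]

P_FLOOR = 1e-12

#: default parameter bounds, in coded size units (Delta = 1):
#: mu0 within 3 Delta of the design mean, broad dispersions, decay in [0, 3]
DEFAULT_BOUNDS = ((-3.0, 3.0), (1e-3, 10.0), (1e-3, 5.0), (0.0, 3.0))
CONSTANT_BOUNDS = ((-3.0, 3.0), (1e-3, 5.0))


@dataclass
class FitConfig:
    n_starts: int = 50
    n_top: int = 20
    bounds: tuple = DEFAULT_BOUNDS
    seed: int = 0
    stage1_maxfev: int = 50
    stage2_maxfev: int = 100_000
    tol: float = 1e-7


@dataclass
class FitResult:
    params_hat: ObserverParams | dict
    loglik: float
    n_trials_used: int
    converged: bool
    starts_table: pd.DataFrame = field(repr=False)
    model: str = "bmbu"


@dataclass
class ModelComparison:
    aic_bmbu: float
    aic_const: float
    delta_aic: float
    nagelkerke_bmbu: float
    nagelkerke_const: float


def _nll_from_probs(p_large: np.ndarray, choice: np.ndarray) -> float:
    p = np.where(choice == 1, p_large, 1.0 - p_large)
    return float(-np.sum(np.log(np.clip(p, P_FLOOR, None))))


def neg_log_likelihood(table: pd.DataFrame, params: ObserverParams) -> float:
    """Negative log-likelihood (nats) of the valid choices under the model."""
    design = prepare_design(table)
    return _nll_design(design, params.as_array())


def _nll_design(design: dict, theta: np.ndarray) -> float:
    mu0, sigma0, sigma_m, kappa = theta
    params = ObserverParams(mu0, max(sigma0, 1e-8), max(sigma_m, 1e-8), max(kappa, 0.0))
    valid = design["valid"]
    if not valid.any():
        raise ValueError("no valid trials to fit")
    p = _choice_probability_padded(
        design["stimulus"][valid], design["history"][valid], params
    )
    return _nll_from_probs(p, design["choice"][valid])


def neg_log_likelihood_constant(table: pd.DataFrame, mu0: float, sigma_m: float) -> float:
    design = prepare_design(table)
    return _nll_constant(design, np.array([mu0, sigma_m]))


def _nll_constant(design: dict, theta: np.ndarray) -> float:
    mu0, sigma_m = theta
    valid = design["valid"]
    if not valid.any():
        raise ValueError("no valid trials to fit")
    from scipy.special import ndtr

    p = ndtr((design["stimulus"][valid] - mu0) / max(sigma_m, 1e-8))
    return _nll_from_probs(p, design["choice"][valid])


def _multistart(nll, bounds, config: FitConfig) -> tuple[np.ndarray, float, pd.DataFrame]:
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    inits = lo + rng.random((config.n_starts, len(bounds))) * (hi - lo)

    rows = []
    stage1 = []
    for x0 in inits:
        res = minimize(
            nll, x0, method="Nelder-Mead", bounds=bounds,
            options={"maxfev": config.stage1_maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        stage1.append((res.fun, res.x, x0))
        rows.append({"stage": 1, "init": x0, "final_nll": res.fun})
    stage1.sort(key=lambda r: r[0])
    candidates = [x for _, x, _ in stage1[: config.n_top]]

    def refine(xs):
        out = []
        for x0 in xs:
            res = minimize(
                nll, x0, method="Nelder-Mead", bounds=bounds,
                options={
                    "maxfev": config.stage2_maxfev,
                    "xatol": config.tol,
                    "fatol": config.tol,
                },
            )
            out.append((res.fun, res.x))
            rows.append({"stage": 2, "init": x0, "final_nll": res.fun})
        return out

    stage2 = refine(candidates)
    stage3 = refine([x for _, x in stage2])
    best_fun, best_x = min(stage2 + stage3, key=lambda r: r[0])
    return best_x, best_fun, pd.DataFrame(rows)


def fit_bmbu(table: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit the boundary-updating observer to one subject's choices.

    Deterministic for a fixed ``config.seed``.  Returns the best parameter
    set over the multistart schedule with the per-start bookkeeping attached.
    """
    config = config or FitConfig()
    design = prepare_design(table)
    best_x, best_fun, starts = _multistart(
        lambda th: _nll_design(design, th), config.bounds, config
    )
    return FitResult(
        params_hat=ObserverParams(*best_x),
        loglik=-best_fun,
        n_trials_used=int(design["valid"].sum()),
        converged=bool(np.isfinite(best_fun)),
        starts_table=starts,
        model="bmbu",
    )


def fit_constant(table: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit the constant-boundary control model (parameters mu0, sigma_m)."""
    config = config or FitConfig(bounds=CONSTANT_BOUNDS)
    bounds = config.bounds if len(config.bounds) == 2 else CONSTANT_BOUNDS
    design = prepare_design(table)
    best_x, best_fun, starts = _multistart(
        lambda th: _nll_constant(design, th), bounds, config
    )
    return FitResult(
        params_hat={"mu0": float(best_x[0]), "sigma_m": float(best_x[1])},
        loglik=-best_fun,
        n_trials_used=int(design["valid"].sum()),
        converged=bool(np.isfinite(best_fun)),
        starts_table=starts,
        model="constant",
    )


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and intercept-only log-likelihoods."""
    num = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik))
    den = 1.0 - np.exp((2.0 / n) * loglik_null)
    return float(num / den)


def _null_loglik(choice: np.ndarray) -> float:
    p = np.clip(choice.mean(), P_FLOOR, 1 - P_FLOOR)
    k = choice.sum()
    n = choice.size
    return float(k * np.log(p) + (n - k) * np.log1p(-p))


def compare_models(fit_b: FitResult, fit_c: FitResult, table: pd.DataFrame) -> ModelComparison:
    """AIC and Nagelkerke R^2 for the updating vs constant-boundary fits.

    Both fits must have been computed on the identical set of valid trials;
    AIC uses k = 4 (updating) and k = 2 (constant) parameters.
    """
    if fit_b.n_trials_used != fit_c.n_trials_used:
        raise ValueError("fits were computed on different valid-trial sets")
    design = prepare_design(table)
    choice = design["choice"][design["valid"]]
    T = choice.size
    if T != fit_b.n_trials_used:
        raise ValueError("table does not match the fitted trial set")
    ll0 = _null_loglik(choice)
    aic_b = 2 * 4 - 2 * fit_b.loglik
    aic_c = 2 * 2 - 2 * fit_c.loglik
    return ModelComparison(
        aic_bmbu=aic_b,
        aic_const=aic_c,
        delta_aic=aic_b - aic_c,
        nagelkerke_bmbu=nagelkerke_r2(fit_b.loglik, ll0, T),
        nagelkerke_const=nagelkerke_r2(fit_c.loglik, ll0, T),
    )
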