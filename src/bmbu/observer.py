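"""Generative model and inference equations of the boundary-updating observer.

The observer classifies a ring size as *small* or *large* relative to an
internal class boundary.  Four parameters govern the model:

* ``mu0``    -- prior mean of the typical stimulus size (size units),
* ``sigma0`` -- prior standard deviation (> 0),
* ``sigma_m``-- standard deviation of the sensory measurement noise (> 0),
* ``kappa``  -- memory-decay rate; a measurement retrieved from ``i`` trials
  back carries noise ``sigma_m * (1 + kappa) ** i``.

On every trial the observer (i) infers the current stimulus size ``s`` from a
noisy measurement ``m`` by conjugate-normal updating, (ii) infers the class
boundary ``b`` as the posterior mode of the typical size given up to
``MAX_LAGS`` retrieved measurements from preceding trials of the same run,
(iii) computes the decision variable ``v = P(s > b)``, chooses *large* when
``v > 0.5``, and carries a decision uncertainty ``u`` equal to the
minority-side tail probability.

Because boundary inference draws fresh retrievals every trial, the latent
states at trial ``t`` depend only on the stimulus history, never on the
observer's own past choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "MAX_LAGS",
    "ObserverParams",
    "StimulusInference",
    "BoundaryInference",
    "Decision",
    "memory_sd",
    "infer_stimulus",
    "infer_boundary",
    "decide",
    "choice_probability",
    "choice_probability_mc",
    "constant_boundary_probability",
    "simulate_observer",
]

#: maximum number of past measurements the observer can retrieve
MAX_LAGS = 7


@dataclass(frozen=True)
class ObserverParams:
    """The four generative parameters of one observer."""

    mu0: float
    sigma0: float
    sigma_m: float
    kappa: float

    def __post_init__(self) -> None:
        vals = (self.mu0, self.sigma0, self.sigma_m, self.kappa)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("observer parameters must be finite")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu0, self.sigma0, self.sigma_m, self.kappa])


@dataclass(frozen=True)
class StimulusInference:
    mu_s: float
    sigma_s: float


@dataclass(frozen=True)
class BoundaryInference:
    mu_b: float
    sigma_b: float
    betas: np.ndarray  # beta_0 (prior weight) followed by one weight per lag
    n_lags_used: int


@dataclass(frozen=True)
class Decision:
    v: float
    d: int  # 1 = large, 0 = small
    u: float


def memory_sd(params: ObserverParams, lag: int) -> float:
    """Noise sd of a measurement retrieved from ``lag`` trials back.

    Memory precision decays exponentially: ``sigma_m * (1 + kappa) ** lag``.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    return params.sigma_m * (1.0 + params.kappa) ** lag


def infer_stimulus(m: float, params: ObserverParams) -> StimulusInference:
    """Posterior of the current stimulus size given the measurement ``m``.

    Conjugate-normal combination of the prior N(mu0, sigma0) with the
    likelihood N(m, sigma_m).
    """
    if not np.isfinite(m):
        raise ValueError("measurement must be finite")
    v0 = params.sigma0**2
    vm = params.sigma_m**2
    mu_s = (v0 * m + vm * params.mu0) / (v0 + vm)
    sigma_s = params.sigma0 * params.sigma_m / np.sqrt(v0 + vm)
    return StimulusInference(mu_s=mu_s, sigma_s=sigma_s)


def infer_boundary(
    retrieved: Sequence[tuple[int, float]], params: ObserverParams
) -> BoundaryInference:
    """Posterior of the class boundary given retrieved past measurements.

    ``retrieved`` is a sequence of ``(lag, value)`` pairs with distinct lags
    >= 1.  The boundary is the precision-weighted combination of the prior
    and the retrievals, with weights ``beta_0 ∝ sigma0**-2`` and
    ``beta_i ∝ memory_sd(lag_i)**-2``, normalised to sum to one.  An empty
    sequence leaves the boundary at the prior: ``(mu0, sigma0)``.
    """
    lags = [lag for lag, _ in retrieved]
    if len(set(lags)) != len(lags):
        raise ValueError("duplicate lags in retrieved measurements")
    if any(lag < 1 for lag in lags):
        raise ValueError("lags must be >= 1")
    if len(lags) > MAX_LAGS:
        raise ValueError(f"at most {MAX_LAGS} retrievals can be used")
    if not retrieved:
        return BoundaryInference(
            mu_b=params.mu0,
            sigma_b=params.sigma0,
            betas=np.array([1.0]),
            n_lags_used=0,
        )
    values = np.array([val for _, val in retrieved], dtype=float)
    sds = np.array([memory_sd(params, lag) for lag in lags])
    prec = np.concatenate([[params.sigma0**-2], sds**-2.0])
    betas = prec / prec.sum()
    mu_b = betas[0] * params.mu0 + betas[1:] @ values
    sigma_b = np.sqrt(
        betas[0] ** 2 * params.sigma0**2 + np.sum(betas[1:] ** 2 * sds**2)
    )
    return BoundaryInference(
        mu_b=mu_b, sigma_b=sigma_b, betas=betas, n_lags_used=len(lags)
    )


def decide(
    s: float,
    b: float,
    sigma_s: float,
    sigma_b: float,
    rng: np.random.Generator | None = None,
) -> Decision:
    """Decision variable, choice, and uncertainty from inferred s and b.

    ``v = Phi[(s - b) / sqrt(sigma_s**2 + sigma_b**2)]``; *large* iff
    ``v > 0.5``; the measure-zero tie ``v == 0.5`` is resolved by a fair coin
    drawn from ``rng`` so runs are reproducible under a seed.
    ``u = Phi[-|s - b| / sqrt(sigma_s**2 + sigma_b**2)]`` is the probability
    that the committed choice is incorrect.
    """
    if sigma_s < 0 or sigma_b < 0:
        raise ValueError("dispersions must be non-negative")
    denom = np.hypot(sigma_s, sigma_b)
    if denom == 0.0:
        if s == b:
            raise ValueError("degenerate input: s == b with zero dispersion")
        v = 1.0 if s > b else 0.0
    else:
        v = float(ndtr((s - b) / denom))
    if v > 0.5:
        d = 1
    elif v < 0.5:
        d = 0
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        d = int(rng.integers(2))
    u = float(ndtr(-abs(s - b) / denom)) if denom > 0 else 0.0
    return Decision(v=v, d=d, u=u)


def _history_moments(
    history: np.ndarray, params: ObserverParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boundary-mean weights and retrieval sds for a (possibly padded) history.

    ``history`` is an array of shape (..., MAX_LAGS) with NaN where a lag is
    unavailable (run start).  Returns ``beta0``, ``betas`` (..., MAX_LAGS)
    and ``sds`` (MAX_LAGS,); unavailable lags get weight 0.
    """
    lags = np.arange(1, MAX_LAGS + 1)
    sds = params.sigma_m * (1.0 + params.kappa) ** lags
    avail = np.isfinite(history)
    prec = np.where(avail, sds**-2.0, 0.0)
    total = params.sigma0**-2 + prec.sum(axis=-1)
    beta0 = params.sigma0**-2 / total
    betas = prec / total[..., None]
    return beta0, betas, sds


def choice_probability(
    stim_now: float,
    stim_history: Sequence[float],
    params: ObserverParams,
) -> float:
    """Closed-form probability of a *large* choice given the stimulus history.

    Marginalising the measurement and retrieval noise, the posterior means
    mu_s and mu_b are jointly Gaussian, so

        P(large) = Phi[(E[mu_s] - E[mu_b]) / sqrt(Var mu_s + Var mu_b)]

    with ``E[mu_s] = a*S(t) + (1-a)*mu0`` where ``a = sigma0^2 /
    (sigma0^2 + sigma_m^2)``, ``Var mu_s = a^2 sigma_m^2``, and the boundary
    moments given by the precision weights over the available lags.
    ``stim_history`` is ordered by lag (element 0 = previous trial) and may be
    empty, in which case the boundary sits at the prior mean with zero
    marginal variance.
    """
    if len(stim_history) > MAX_LAGS:
        raise ValueError(f"history length must be <= {MAX_LAGS}")
    hist = np.full(MAX_LAGS, np.nan)
    hist[: len(stim_history)] = np.asarray(stim_history, dtype=float)
    return float(_choice_probability_padded(np.array([stim_now]), hist[None, :], params)[0])


def _choice_probability_padded(
    stim_now: np.ndarray, history: np.ndarray, params: ObserverParams
) -> np.ndarray:
    """Vectorised closed-form P(large); ``history`` is (T, MAX_LAGS), NaN-padded."""
    v0 = params.sigma0**2
    vm = params.sigma_m**2
    a = v0 / (v0 + vm)
    e_mu_s = a * stim_now + (1.0 - a) * params.mu0
    var_mu_s = a**2 * vm
    beta0, betas, sds = _history_moments(history, params)
    hist0 = np.where(np.isfinite(history), history, 0.0)
    e_mu_b = beta0 * params.mu0 + np.sum(betas * hist0, axis=-1)
    var_mu_b = np.sum(betas**2 * sds**2, axis=-1)
    return ndtr((e_mu_s - e_mu_b) / np.sqrt(var_mu_s + var_mu_b))


def choice_probability_mc(
    stim_now: float,
    stim_history: Sequence[float],
    params: ObserverParams,
    n: int = 10**6,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of :func:`choice_probability` (test oracle).

    Samples the measurement and the retrievals independently and counts how
    often the inferred stimulus exceeds the inferred boundary.
    """
    rng = np.random.default_rng(seed)
    v0 = params.sigma0**2
    vm = params.sigma_m**2
    a = v0 / (v0 + vm)
    m = rng.normal(stim_now, params.sigma_m, size=n)
    mu_s = a * m + (1.0 - a) * params.mu0
    hist = np.full(MAX_LAGS, np.nan)
    hist[: len(stim_history)] = np.asarray(stim_history, dtype=float)
    beta0, betas, sds = _history_moments(hist, params)
    mu_b = np.full(n, beta0 * params.mu0)
    for i in range(MAX_LAGS):
        if np.isfinite(hist[i]):
            r = rng.normal(hist[i], sds[i], size=n)
            mu_b += betas[i] * r
    return float(np.mean(mu_s > mu_b))


def constant_boundary_probability(stim_now: float, mu0: float, sigma_m: float) -> float:
    """P(large) under the constant-boundary control model.

    The stimulus estimate is drawn from N(S(t), sigma_m) and compared against
    a fixed boundary mu0 with zero boundary uncertainty.
    """
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    return float(ndtr((stim_now - mu0) / sigma_m))


def simulate_observer(
    stimuli: np.ndarray,
    run_ids: np.ndarray,
    params: ObserverParams,
    n_reps: int = 1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate the observer over a stimulus sequence.

    Parameters
    ----------
    stimuli : (T,) array of presented sizes (coded units).
    run_ids : (T,) array of run labels; retrieval never crosses run boundaries.
    n_reps : number of independent repetitions of the whole session.
    seed : seed for all measurement/retrieval noise and tie-breaking.

    Returns
    -------
    dict with arrays of shape (n_reps, T): ``s``, ``b``, ``v``, ``u``
    (latent states) and ``d`` (choices, 1 = large); plus ``sigma_s`` (scalar)
    and ``sigma_b`` (T,), the deterministic dispersions.

    Each repetition draws a fresh measurement for the current trial and fresh
    retrievals for every available lag (up to :data:`MAX_LAGS`, same run
    only), so trials are conditionally independent given the stimulus
    sequence.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    stimuli = np.asarray(stimuli, dtype=float)
    run_ids = np.asarray(run_ids)
    T = stimuli.size
    rng = np.random.default_rng(seed)

    hist = _stimulus_history(stimuli, run_ids)
    beta0, betas, sds = _history_moments(hist, params)
    v0 = params.sigma0**2
    vm = params.sigma_m**2
    a = v0 / (v0 + vm)
    sigma_s = params.sigma0 * params.sigma_m / np.sqrt(v0 + vm)
    sigma_b = np.sqrt(beta0**2 * v0 + np.sum(betas**2 * sds**2, axis=-1))

    m = rng.normal(stimuli, params.sigma_m, size=(n_reps, T))
    s = a * m + (1.0 - a) * params.mu0

    hist0 = np.where(np.isfinite(hist), hist, 0.0)
    avail = np.isfinite(hist)
    # retrieval noise: fresh per rep, trial and lag, only where available
    noise = rng.standard_normal((n_reps, T, MAX_LAGS)) * sds * avail
    b = beta0 * params.mu0 + np.sum(betas * (hist0 + noise), axis=-1)

    denom = np.sqrt(sigma_s**2 + sigma_b**2)
    z = (s - b) / denom
    v = ndtr(z)
    u = ndtr(-np.abs(z))
    d = (v > 0.5).astype(np.int8)
    ties = v == 0.5
    if np.any(ties):
        d[ties] = rng.integers(2, size=int(ties.sum()))
    return {
        "s": s,
        "b": b,
        "v": v,
        "u": u,
        "d": d,
        "sigma_s": sigma_s,
        "sigma_b": sigma_b,
    }


def _stimulus_history(stimuli: np.ndarray, run_ids: np.ndarray) -> np.ndarray:
    """(T, MAX_LAGS) matrix of past stimuli within-run, NaN where unavailable."""
    T = stimuli.size
    hist = np.full((T, MAX_LAGS), np.nan)
    for t in range(T):
        for i in range(1, MAX_LAGS + 1):
            j = t - i
            if j < 0 or run_ids[j] != run_ids[t]:
                break
            hist[t, i - 1] = stimuli[j]
    return hist
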