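"""Early-visual-cortex machinery: eccentricity tuning, readouts, adaptation.

The size-encoding signal is read out from eccentricity-binned BOLD responses.
Each bin's eccentricity-tuning curve is a Gaussian ``g_e(eps) =
exp(-(eps - e)^2 / (2 sigma^2))`` fitted to responses to traversing ring
stimuli.  After subtracting the across-bin mean at every time frame (the
"tuned response"), a per-trial scalar size signal is extracted as a weighted
sum over bins under one of three weighting schemes (uniform sign,
discriminability, log-likelihood ratio).  Regressing that signal on the
current stimulus, the previous stimulus and the previous choice quantifies
stimulus drive and sensory adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .behavior import add_lagged_columns

__all__ = [
    "EccentricityTuning",
    "ReadoutWeights",
    "double_gamma_hirf",
    "fit_eccentricity_tuning",
    "tuned_response",
    "readout_weights",
    "extract_signal",
    "adaptation_regression",
    "drop_high_variance_voxels",
]

SCHEMES = ("uniform", "discriminability", "loglik_ratio")


@dataclass
class EccentricityTuning:
    e: float  # peak eccentricity (deg)
    sigma_tune: float  # tuning width (deg)
    gain: float
    baseline: float
    rss: float
    degenerate: bool = False


@dataclass
class ReadoutWeights:
    scheme: str
    w: np.ndarray  # one weight per eccentricity bin
    r_s: float
    r_m: float
    r_l: float


def double_gamma_hirf(n_frames: int = 6, tr: float = 2.2) -> np.ndarray:
    """Unit-sum double-gamma hemodynamic kernel sampled at the frame rate."""
    t = np.arange(n_frames) * tr
    peak = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    s = peak.sum()
    return peak / s


def fit_eccentricity_tuning(
    voxel_ts: np.ndarray,
    stim_movie: np.ndarray,
    eccs: np.ndarray,
    hirf: np.ndarray,
    e_grid: np.ndarray | None = None,
) -> EccentricityTuning:
    """Fit a Gaussian eccentricity-tuning curve to one voxel's time series.

    The predicted response is ``conv(sum_eps stim(eps, t) g_e(eps), hirf) *
    gain + baseline``; gain and baseline are profiled by linear least squares
    while (e, sigma) are searched over a grid and refined by a simplex.
    A flat time series is flagged degenerate and not fitted.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    if np.ptp(voxel_ts) == 0:
        return EccentricityTuning(np.nan, np.nan, 0.0, float(voxel_ts[0]), 0.0, True)
    eccs = np.asarray(eccs, dtype=float)
    if e_grid is None:
        e_grid = np.linspace(eccs.min(), eccs.max(), 13)

    def predict_neural(e, sig):
        g = np.exp(-((eccs[:, None] - e) ** 2) / (2 * sig**2))
        n_t = (stim_movie * g).sum(axis=0)
        return np.convolve(n_t, hirf)[: len(voxel_ts)]

    def rss_of(theta):
        e, log_sig = theta
        x = predict_neural(e, np.exp(log_sig))
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, voxel_ts, rcond=None)
        resid = voxel_ts - A @ coef
        return float(resid @ resid), coef

    best = None
    for e0 in e_grid:
        for sig0 in (0.5, 1.0, 2.0):
            val, _ = rss_of((e0, np.log(sig0)))
            if best is None or val < best[0]:
                best = (val, (e0, np.log(sig0)))
    res = minimize(lambda th: rss_of(th)[0], best[1], method="Nelder-Mead")
    rss, coef = rss_of(res.x)
    e_hat, sig_hat = res.x[0], float(np.exp(res.x[1]))
    gain, base = float(coef[0]), float(coef[1])
    degenerate = abs(gain) < 1e-8
    return EccentricityTuning(
        e=float(e_hat), sigma_tune=sig_hat, gain=gain, baseline=base,
        rss=rss, degenerate=degenerate,
    )


def tuned_response(rr: np.ndarray) -> np.ndarray:
    """Subtract the across-bin mean at every time frame (bins on axis 0)."""
    rr = np.asarray(rr, dtype=float)
    if rr.shape[0] < 2:
        raise ValueError("need at least 2 eccentricity bins")
    return rr - rr.mean(axis=0, keepdims=True)


def readout_weights(
    scheme: str,
    peak_eccs: np.ndarray,
    tuning_widths: np.ndarray | float,
    r_s: float,
    r_m: float,
    r_l: float,
) -> ReadoutWeights:
    """Per-bin weights for reading out the size signal.

    uniform: sign(e - r_m) in {-1, 0, +1}.
    discriminability: ``g_e(r_l) - g_e(r_s)`` minus its across-bin mean.
    loglik_ratio: ``-(e - r_l)^2 / (2 sigma_l^2) + (e - r_s)^2 /
    (2 sigma_s^2)`` minus its across-bin mean, using the tuning widths of the
    bins nearest the L- and S-ring radii.
    """
    if r_s >= r_l:
        raise ValueError("r_s must be smaller than r_l")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    e = np.asarray(peak_eccs, dtype=float)
    sig = np.broadcast_to(np.asarray(tuning_widths, dtype=float), e.shape)
    if scheme == "uniform":
        w = np.sign(e - r_m)
    elif scheme == "discriminability":
        def g(r):
            return np.exp(-((e - r) ** 2) / (2 * sig**2))
        raw = g(r_l) - g(r_s)
        w = raw - raw.mean()
    else:
        sig_l = sig[np.argmin(np.abs(e - r_l))]
        sig_s = sig[np.argmin(np.abs(e - r_s))]
        raw = -((e - r_l) ** 2) / (2 * sig_l**2) + ((e - r_s) ** 2) / (2 * sig_s**2)
        w = raw - raw.mean()
    return ReadoutWeights(scheme=scheme, w=w, r_s=r_s, r_m=r_m, r_l=r_l)


def extract_signal(
    tr: np.ndarray, weights: ReadoutWeights, frames: int | tuple[int, ...] = 3
) -> np.ndarray:
    """Per-trial size signal: weighted bin sum at the selected frame(s).

    ``tr`` has shape (n_bins, n_trials, n_frames).  ``frames`` selects the
    within-trial frame (default the fourth, index 3) or several frames to
    average.  Positive values read as "larger perceived size".
    """
    tr = np.asarray(tr, dtype=float)
    frames = (frames,) if np.isscalar(frames) else tuple(frames)
    if any(f < 0 or f >= tr.shape[2] for f in frames):
        raise IndexError(f"frame out of range for {tr.shape[2]} frames")
    sel = tr[:, :, list(frames)].mean(axis=2)
    return weights.w @ sel


def adaptation_regression(
    signal: np.ndarray, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject linear regression of the size signal on S(t), S(t-1), D(t-1).

    ``signal`` is the per-trial scalar readout aligned with ``table`` rows.
    Returns the OLS coefficients; a positive S(t) coefficient is stimulus
    drive, a negative S(t-1) coefficient is sensory adaptation.
    """
    t = add_lagged_columns(table, n_lags=1).assign(signal=np.asarray(signal))
    t = t.dropna(subset=["stim_lag1", "choice_lag1"])
    if "valid" in t.columns:
        t = t[t["valid"]]
    X = np.column_stack([
        np.ones(len(t)),
        t["stimulus"].to_numpy(dtype=float),
        t["stim_lag1"].to_numpy(dtype=float),
        t["choice_lag1"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient adaptation design")
    y = t["signal"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(t) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    names = ["intercept", "stim", "stim_lag1", "choice_lag1"]
    return pd.DataFrame({"coef": coef, "se": se}, index=names)


def drop_high_variance_voxels(
    ts: np.ndarray, factor: float = 10.0
) -> np.ndarray:
    """Mask of voxels kept after the blood-vessel-clamp exclusion.

    A voxel (axis 0) is dropped when its temporal variance exceeds ``factor``
    times the median variance over voxels.
    """
    var = np.var(np.asarray(ts, dtype=float).reshape(ts.shape[0], -1), axis=1)
    return var <= factor * np.median(var)
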