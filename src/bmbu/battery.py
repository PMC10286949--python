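"""The regression battery a decoded brain signal must satisfy.

A candidate brain signal for one of the model's latent variables (boundary b,
inferred stimulus s, decision variable v) is accepted only if it satisfies
every regression condition the model's causal structure implies: positive
coverage of the variable it claims to represent (also after orthogonalizing
that variable to its causal offspring), the correct signed relations to the
other latents and to the choice, no relation where the causal graph forbids
one, and the correct multiple-regression profile on the observable stimulus
and choice history.  The battery has 14 conditions for b, 14 for s and 17
for v.

Group-level coefficients come from a linear mixed-effects model with subject
as the grouping factor (random intercept plus a random slope for the focal
regressor in the simple models, intercept-only fallback on convergence
failure).  Significance is one- or two-tailed per condition; "must not be
significant" conditions pass when the tail p-value is above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .behavior import add_lagged_columns

__all__ = ["BatteryReport", "battery_spec", "run_battery", "battery_condition_count"]

# (index, regressor, model, threshold, must_be_significant, tail, fdr)
_SIMPLE, _MULT = "simple", "multiple"

_BATTERY = {
    "b": [
        (1, "b", _SIMPLE, 0.001, True, "right", False),
        (2, "b", _SIMPLE, 0.05, True, "right", True),
        (3, "b_perp_v", _SIMPLE, 0.05, True, "right", False),
        (4, "b_perp_d", _SIMPLE, 0.05, True, "right", False),
        (5, "s", _SIMPLE, 0.05, False, "both", False),
        (6, "v", _SIMPLE, 0.05, True, "left", False),
        (7, "v_perp_b", _SIMPLE, 0.05, False, "left", False),
        (8, "d", _SIMPLE, 0.05, True, "left", False),
        (9, "u", _SIMPLE, 0.05, False, "both", False),
        (10, "S", _MULT, 0.05, False, "both", False),
        (11, "S1", _MULT, 0.05, True, "right", False),
        (12, "S2", _MULT, 0.05, False, "left", False),
        (13, "D1", _MULT, 0.05, False, "both", False),
        (14, "D2", _MULT, 0.05, False, "both", False),
    ],
    "s": [
        (1, "s", _SIMPLE, 0.001, True, "right", False),
        (2, "s", _SIMPLE, 0.05, True, "right", True),
        (3, "s_perp_v", _SIMPLE, 0.05, True, "right", False),
        (4, "s_perp_d", _SIMPLE, 0.05, True, "right", False),
        (5, "b", _SIMPLE, 0.05, False, "both", False),
        (6, "v", _SIMPLE, 0.05, True, "right", False),
        (7, "v_perp_s", _SIMPLE, 0.05, False, "right", False),
        (8, "d", _SIMPLE, 0.05, True, "right", False),
        (9, "u", _SIMPLE, 0.05, False, "both", False),
        (10, "S", _MULT, 0.05, True, "right", False),
        (11, "S1", _MULT, 0.05, False, "both", False),
        (12, "S2", _MULT, 0.05, False, "both", False),
        (13, "D1", _MULT, 0.05, False, "both", False),
        (14, "D2", _MULT, 0.05, False, "both", False),
    ],
    "v": [
        (1, "v", _SIMPLE, 0.001, True, "right", False),
        (2, "v", _SIMPLE, 0.05, True, "right", True),
        (3, "v_perp_b", _SIMPLE, 0.05, True, "right", False),
        (4, "v_perp_s", _SIMPLE, 0.05, True, "right", False),
        (5, "v_perp_d", _SIMPLE, 0.05, True, "right", False),
        (6, "b", _SIMPLE, 0.05, True, "left", False),
        (7, "b_perp_v", _SIMPLE, 0.05, False, "left", False),
        (8, "s", _SIMPLE, 0.05, True, "right", False),
        (9, "s_perp_v", _SIMPLE, 0.05, False, "right", False),
        (10, "d", _SIMPLE, 0.05, True, "right", False),
        (11, "u", _SIMPLE, 0.05, False, "both", False),
        (12, "S", _MULT, 0.05, True, "right", False),
        (13, "S1", _MULT, 0.05, True, "left", False),
        (14, "S2", _MULT, 0.05, False, "right", False),
        (15, "D", _MULT, 0.05, True, "right", False),
        (16, "D1", _MULT, 0.05, False, "both", False),
        (17, "D2", _MULT, 0.05, False, "both", False),
    ],
}

_MULT_REGS = {
    "b": ["S", "S1", "S2", "D1", "D2"],
    "s": ["S", "S1", "S2", "D1", "D2"],
    "v": ["S", "S1", "S2", "D", "D1", "D2"],
}


def battery_spec(variable: str) -> list[tuple]:
    if variable not in _BATTERY:
        raise ValueError("variable must be one of 'b', 's', 'v'")
    return list(_BATTERY[variable])


def battery_condition_count(variable: str) -> int:
    return len(battery_spec(variable))


@dataclass
class BatteryReport:
    variable: str
    tests: pd.DataFrame  # per condition: coefficient, p, pass
    passed: bool


def _residualize(x: np.ndarray, onto: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones_like(onto), onto])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ coef


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _subject_frame(
    y: np.ndarray, latents: pd.DataFrame, table: pd.DataFrame, subject: int
) -> pd.DataFrame:
    """Aligned per-subject frame of the decoded signal and all regressors."""
    t = add_lagged_columns(table, n_lags=2)
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "b": latents["b"].to_numpy(),
            "s": latents["s"].to_numpy(),
            "v": latents["v"].to_numpy(),
            "u": latents["u"].to_numpy(),
            "d": latents["d"].to_numpy(dtype=float),
            "S": t["stimulus"].to_numpy(dtype=float),
            "S1": t["stim_lag1"].to_numpy(dtype=float),
            "S2": t["stim_lag2"].to_numpy(dtype=float),
            "D": t["choice"].to_numpy(dtype=float),
            "D1": t["choice_lag1"].to_numpy(dtype=float),
            "D2": t["choice_lag2"].to_numpy(dtype=float),
        }
    )
    if "valid" in table.columns:
        df = df[table["valid"].to_numpy()]
    df = df.dropna()
    for a, b in (
        ("b", "v"), ("b", "d"), ("s", "v"), ("s", "d"),
        ("v", "b"), ("v", "s"), ("v", "d"),
    ):
        df[f"{a}_perp_{b}"] = _residualize(df[a].to_numpy(), df[b].to_numpy())
    for col in df.columns:
        df[col] = _zscore(df[col].to_numpy())
    df["subject"] = subject
    return df


def _mixed_coef(data: pd.DataFrame, regs: list[str], focal: str) -> tuple[float, float]:
    """Fixed-effect coefficient and z statistic for ``focal`` from a GLMM.

    Random intercept plus a random slope for the focal regressor; falls back
    to a random intercept only, then to pooled OLS with subject-cluster
    robust errors, on convergence failure.
    """
    exog = sm.add_constant(data[regs].to_numpy())
    endog = data["y"].to_numpy()
    groups = data["subject"].to_numpy()
    k = regs.index(focal) + 1
    for re_cols in ([focal], None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if re_cols is None:
                    exog_re = np.ones((len(data), 1))
                else:
                    exog_re = sm.add_constant(data[re_cols].to_numpy())
                model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
                res = model.fit(reml=False, maxiter=200)
            coef = res.fe_params[k]
            se = res.bse_fe[k]
            if np.isfinite(coef) and np.isfinite(se) and se > 0:
                return float(coef), float(coef / se)
        except Exception:
            continue
    res = sm.OLS(endog, exog).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return float(res.params[k]), float(res.tvalues[k])


def _tail_p(z: float, tail: str) -> float:
    if tail == "right":
        return float(stats.norm.sf(z))
    if tail == "left":
        return float(stats.norm.cdf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def run_battery(
    decoded: list[np.ndarray],
    latents: list[pd.DataFrame],
    tables: list[pd.DataFrame],
    variable: str,
) -> BatteryReport:
    """Run every regression condition of the battery for one decoded signal.

    ``decoded``, ``latents`` (per-trial b, s, v, u, d estimates) and
    ``tables`` are per-subject, aligned on trials.  Orthogonalized
    regressors are residuals computed within subject; all columns are
    z-scored within subject before pooling into the mixed model.

    The FDR-flagged condition is evaluated at its raw p here; when the battery
    sweeps many searchlight centers the caller adjusts across centers.
    """
    if not len(decoded) == len(latents) == len(tables):
        raise ValueError("decoded, latents and tables must align per subject")
    for lat in latents:
        missing = {"b", "s", "v", "u", "d"} - set(lat.columns)
        if missing:
            raise ValueError(f"latents missing columns: {sorted(missing)}")
    frames = [
        _subject_frame(y, lat, tab, i)
        for i, (y, lat, tab) in enumerate(zip(decoded, latents, tables))
    ]
    data = pd.concat(frames, ignore_index=True)

    rows = []
    mult_regs = _MULT_REGS[variable]
    mult_cache: dict[str, tuple[float, float]] = {}
    for idx, reg, model, thr, must_sig, tail, fdr in battery_spec(variable):
        if model == _SIMPLE:
            coef, z = _mixed_coef(data, [reg], reg)
        else:
            if reg not in mult_cache:
                for r in mult_regs:
                    mult_cache[r] = _mixed_coef(data, mult_regs, r)
            coef, z = mult_cache[reg]
        p = _tail_p(z, tail)
        ok = (p < thr) if must_sig else (p >= thr)
        rows.append(
            {
                "index": idx,
                "regressor": reg,
                "model": model,
                "tail": tail,
                "threshold": thr,
                "must_be_significant": must_sig,
                "fdr": fdr,
                "coef": coef,
                "p": p,
                "passed": ok,
            }
        )
    tests = pd.DataFrame(rows)
    return BatteryReport(variable=variable, tests=tests, passed=bool(tests["passed"].all()))
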