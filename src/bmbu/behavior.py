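"""Behavioral quantification of history biases.

Three families of analyses:

* conditioned psychometric summaries -- differences in the proportion of
  *large* choices (PL) conditioned on the previous stimulus or the previous
  choice, cell-averaged over the complementary factors; a negative
  previous-stimulus effect is the signature of repulsive bias;
* the lagged logistic history kernel -- per-subject logistic regression of
  the current choice on the z-scored current stimulus, five stimulus lags and
  five choice lags;
* average marginal effects (AME) -- the mean derivative of the choice
  probability with respect to a focal trial signal, compared across nested
  control sets (previous stimulus, current stimulus, both) to ask whether the
  focal signal mediates the history information; the previous choice is always
  controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .trials import require_columns

__all__ = [
    "HistoryKernel",
    "AMEResult",
    "pl_differences",
    "fit_history_kernel",
    "compute_ame",
    "ame_contrast_suite",
    "add_lagged_columns",
]

N_LAGS = 5


@dataclass
class HistoryKernel:
    coef: pd.Series  # intercept, S(t), S(t-1..5), D(t-1..5) on z-scored regressors
    se: pd.Series
    n_trials: int
    separation_flag: bool


@dataclass
class AMEResult:
    per_subject: pd.DataFrame  # one row per subject, one column per variant
    deltas: pd.DataFrame  # paired contrasts with t and p across subjects


def add_lagged_columns(table: pd.DataFrame, n_lags: int = N_LAGS) -> pd.DataFrame:
    """Attach within-run lagged stimulus/choice columns (NaN where unavailable)."""
    require_columns(table, ("run", "stimulus", "choice"))
    group = [c for c in ("subject", "run") if c in table.columns]
    out = table.copy()
    g = out.groupby(group, sort=False)
    for i in range(1, n_lags + 1):
        out[f"stim_lag{i}"] = g["stimulus"].shift(i)
        out[f"choice_lag{i}"] = g["choice"].shift(i)
    return out


def pl_differences(table: pd.DataFrame) -> dict[str, float]:
    """Previous-stimulus and previous-choice effects on the P(large) summaries.

    ``prev_stim_effect``: mean over the (current stimulus x previous choice)
    cells of PL(previous = L) - PL(previous = S).  ``prev_choice_effect``:
    mean over the (current x previous stimulus) cells of
    PL(previous choice = large) - PL(previous choice = small).  Cells with no
    trials on either side are dropped from the mean.
    """
    t = add_lagged_columns(table, n_lags=1)
    t = t.dropna(subset=["stim_lag1", "choice_lag1"])
    if "valid" in t.columns:
        t = t[t["valid"]]
    if t.empty:
        raise ValueError("no usable trials for PL differences")

    def cell_effect(cond_cols: list[str], split_col: str, hi, lo) -> float:
        diffs = []
        for _, cell in t.groupby(cond_cols):
            pl_hi = cell.loc[cell[split_col] == hi, "choice"]
            pl_lo = cell.loc[cell[split_col] == lo, "choice"]
            if len(pl_hi) and len(pl_lo):
                diffs.append(pl_hi.mean() - pl_lo.mean())
        if not diffs:
            raise ValueError("all conditioning cells empty")
        return float(np.mean(diffs))

    return {
        "prev_stim_effect": cell_effect(
            ["stimulus", "choice_lag1"], "stim_lag1", 1.0, -1.0
        ),
        "prev_choice_effect": cell_effect(
            ["stimulus", "stim_lag1"], "choice_lag1", 1, 0
        ),
    }


def fit_history_kernel(table: pd.DataFrame) -> HistoryKernel:
    """Logistic history kernel of one subject's choices.

    Regresses D(t) on z-scored {S(t), S(t-1..5), D(t-1..5)}; trials with
    fewer than five prior same-run trials are dropped.  Perfect separation is
    flagged and handled with an L2-regularized fit.
    """
    t = add_lagged_columns(table)
    cols = (
        ["stimulus"]
        + [f"stim_lag{i}" for i in range(1, N_LAGS + 1)]
        + [f"choice_lag{i}" for i in range(1, N_LAGS + 1)]
    )
    t = t.dropna(subset=cols)
    if "valid" in t.columns:
        t = t[t["valid"]]
    X = t[cols].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    X = sm.add_constant(X)
    y = t["choice"].to_numpy(dtype=float)
    names = ["intercept"] + cols
    separation = False
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params) > 20
        ):
            raise np.linalg.LinAlgError
        coef, se = res.params, res.bse
    except Exception:
        separation = True
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
        coef = res.params
        se = np.full_like(coef, np.nan)
    return HistoryKernel(
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        n_trials=len(t),
        separation_flag=separation,
    )


def compute_ame(
    table: pd.DataFrame,
    focal: str,
    controls: tuple[str, ...] = (),
    include_prev_choice: bool = True,
) -> float:
    """Average marginal effect of ``focal`` on the current choice.

    Fits the logistic model D(t) ~ focal + D(t-1) + controls and returns the
    AME of the focal regressor: ``beta_focal * mean(p * (1 - p))`` over the
    fitted trials (the analytic derivative of the logistic mean; for binary
    regressors this equals the unit-contrast derivative at the fit).
    """
    t = add_lagged_columns(table, n_lags=1)
    cols = [focal] + list(controls) + (["choice_lag1"] if include_prev_choice else [])
    t = t.dropna(subset=cols)
    if "valid" in t.columns:
        t = t[t["valid"]]
    X = sm.add_constant(t[cols].to_numpy(dtype=float))
    cond = np.linalg.cond(X.T @ X)
    if cond > 1e10:
        import warnings

        warnings.warn(f"ill-conditioned AME design (cond={cond:.2g})")
    y = t["choice"].to_numpy(dtype=float)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    p = res.predict(X)
    return float(res.params[1] * np.mean(p * (1.0 - p)))


VARIANTS = {
    "baseline": (),
    "ctrl_prev": ("stim_lag1",),
    "ctrl_curr": ("stimulus",),
    "ctrl_both": ("stim_lag1", "stimulus"),
}

#: the four printed contrasts: does the AME change when a control is added
CONTRASTS = [
    ("baseline", "ctrl_prev"),
    ("baseline", "ctrl_curr"),
    ("ctrl_both", "ctrl_curr"),
    ("ctrl_both", "ctrl_prev"),
]


def ame_contrast_suite(
    cohort_tables: list[pd.DataFrame], focal: str
) -> AMEResult:
    """AME of a focal signal across control variants, compared within subject.

    Computes, per subject, the AME of ``focal`` on the current choice under
    the four control sets (none / previous stimulus / current stimulus /
    both; the previous choice is always controlled), then paired two-tailed
    t tests across subjects for the four change-contrasts.  A focal signal
    that mediates the previous stimulus loses AME when S(t-1) is controlled;
    one that mediates the current stimulus loses it when S(t) is controlled.
    """
    if len(cohort_tables) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for i, tab in enumerate(cohort_tables):
        row = {"subject": i}
        for name, controls in VARIANTS.items():
            try:
                row[name] = compute_ame(tab, focal, controls)
            except Exception:
                row[name] = np.nan
        rows.append(row)
    per_subject = pd.DataFrame(rows).set_index("subject")
    deltas = []
    for a, b in CONTRASTS:
        d = (per_subject[b] - per_subject[a]).dropna()
        tt = stats.ttest_1samp(d, 0.0)
        deltas.append(
            {
                "contrast": f"{b}-{a}",
                "mean_delta": float(d.mean()),
                "t": float(tt.statistic),
                "p": float(tt.pvalue),
                "n": int(len(d)),
            }
        )
    return AMEResult(per_subject=per_subject, deltas=pd.DataFrame(deltas))
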