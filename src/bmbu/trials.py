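"""Trial tables and validity rules.

A trial table is a pandas DataFrame with one row per trial and columns

    subject   observer identifier (optional for single-subject tables)
    run       scan-run label; history never crosses runs
    trial     0-based trial index within run
    stimulus  coded ring size (-1 = small, 0 = medium, +1 = large, in
              threshold units Delta)
    choice    observed classification (1 = large, 0 = small)
    rt        response time in seconds

:func:`exclude_trials` adds a boolean ``valid`` column implementing the
fitting exclusions: the first trial of every run (it has no previous trial)
and trials answered in under 0.3 s (too hasty to reflect a deliberate
decision).  Excluded trials are dropped as outcomes but are retained as
stimulus history for later trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observer import MAX_LAGS, _stimulus_history

__all__ = ["exclude_trials", "prepare_design", "require_columns"]

RT_CUTOFF = 0.3


def require_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"trial table is missing columns: {missing}")


def exclude_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``valid`` flag (first-of-run and RT < 0.3 s invalid)."""
    require_columns(table, ("run",))
    if "rt" not in table.columns:
        raise KeyError("trial table is missing an 'rt' column")
    out = table.copy()
    if out.empty:
        out["valid"] = pd.Series(dtype=bool)
        return out
    group = [c for c in ("subject", "run") if c in out.columns]
    first = out.groupby(group, sort=False).cumcount() == 0
    too_fast = out["rt"].to_numpy() < RT_CUTOFF
    out["valid"] = ~(first.to_numpy() | too_fast)
    return out


def prepare_design(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Precompute the arrays the likelihood needs for one subject's table.

    Returns stimuli, NaN-padded within-run stimulus-history matrix
    (T x MAX_LAGS), choices, and the valid mask.  Fitting operations consume
    this instead of the DataFrame so repeated likelihood evaluations stay
    cheap.
    """
    require_columns(table, ("run", "stimulus", "choice"))
    if "valid" not in table.columns:
        table = exclude_trials(table)
    stim = table["stimulus"].to_numpy(dtype=float)
    runs = table["run"].to_numpy()
    hist = _stimulus_history(stim, runs)
    return {
        "stimulus": stim,
        "history": hist,
        "choice": table["choice"].to_numpy(dtype=int),
        "valid": table["valid"].to_numpy(dtype=bool),
        "run": runs,
    }
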