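"""Experimental design: m-sequence stimulus schedules and threshold calibration.

One scan run presents 26 rings (9 small, 8 medium, 9 large) ordered by a
base-3, power-3 maximal-length shift-register sequence (period 3**3 - 1 = 26),
which nulls the autocorrelation between consecutive sizes.  Runs are rotated so
that every run starts with two medium rings.

The size contrast Delta between rings is calibrated per observer with four
randomly interleaved one-up-two-down staircases (which converge at the
70.7 %-correct point) followed by a maximum-likelihood Weibull fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "RunSchedule",
    "CalibrationResult",
    "generate_msequence",
    "find_primitive_polynomial",
    "build_schedule",
    "simulate_staircase",
    "converged_level",
    "fit_weibull",
    "weibull",
    "schedule_table",
]

#: coded sizes for the three ring labels, in Delta units around the boundary
CODED_SIZE = {"S": -1.0, "M": 0.0, "L": 1.0}
DEFAULT_MAPPING = {0: "M", 1: "L", 2: "S"}


@dataclass(frozen=True)
class RunSchedule:
    labels: tuple[str, ...]
    mapping: dict[int, str]
    rotation: int
    polynomial: tuple[int, ...]

    @property
    def coded(self) -> np.ndarray:
        return np.array([CODED_SIZE[lb] for lb in self.labels])


@dataclass
class CalibrationResult:
    delta_hat: float
    weibull_params: tuple[float, float, float, float]  # scale, shape, guess, lapse
    staircase_trace: pd.DataFrame = field(repr=False)


def _lfsr_sequence(coeffs: tuple[int, ...], base: int, power: int) -> np.ndarray:
    """Shift-register sequence for x^power = c1 x^(power-1) + ... + c_power."""
    state = [1] + [0] * (power - 1)
    period = base**power - 1
    out = np.empty(period, dtype=int)
    for t in range(period):
        out[t] = state[-1]
        new = sum(c * s for c, s in zip(coeffs, reversed(state))) % base
        state = [new] + state[:-1]
    return out


def _full_period(coeffs: tuple[int, ...], base: int, power: int) -> bool:
    seq = _lfsr_sequence(coeffs, base, power)
    period = base**power - 1
    # full period iff every nonzero length-`power` window occurs exactly once
    windows = {
        tuple(np.roll(seq, -k)[:power]) for k in range(period)
    }
    return len(windows) == period


def find_primitive_polynomial(base: int = 3, power: int = 3) -> tuple[int, ...]:
    """Exhaustively search feedback coefficients giving a full-period sequence."""
    for coeffs in product(range(base), repeat=power):
        if coeffs[-1] == 0:
            continue
        if _full_period(coeffs, base, power):
            return coeffs
    raise RuntimeError("no primitive polynomial found")


def generate_msequence(
    base: int = 3, power: int = 3, polynomial: tuple[int, ...] | None = None
) -> np.ndarray:
    """Maximal-length shift-register sequence over {0..base-1}.

    ``polynomial`` gives the feedback coefficients (c1..c_power); if omitted,
    a primitive one is found by exhaustive search with full-period validation.
    Raises if a user-supplied polynomial is not primitive, naming the achieved
    period.
    """
    if not _is_prime(base):
        raise ValueError("base must be prime")
    if power < 2:
        raise ValueError("power must be >= 2")
    if polynomial is None:
        polynomial = find_primitive_polynomial(base, power)
    elif not _full_period(tuple(polynomial), base, power):
        seq = _lfsr_sequence(tuple(polynomial), base, power)
        achieved = _sequence_period(seq)
        raise ValueError(
            f"polynomial {tuple(polynomial)} is not primitive: "
            f"achieved period {achieved}, need {base ** power - 1}"
        )
    return _lfsr_sequence(tuple(polynomial), base, power)


def _sequence_period(seq: np.ndarray) -> int:
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and np.all(seq == np.roll(seq, p)):
            return p
    return n


def _is_prime(n: int) -> bool:
    return n >= 2 and all(n % k for k in range(2, int(n**0.5) + 1))


def build_schedule(
    seq: np.ndarray | None = None,
    mapping: dict[int, str] | None = None,
    n_runs: int = 8,
    seed: int = 0,
) -> list[RunSchedule]:
    """Per-run stimulus label schedules from an m-sequence period.

    Each run is one full period rotated so that it begins with two consecutive
    zero symbols (two medium rings under the default mapping).  Distinct runs
    draw, seeded, among the primitive polynomials and the valid rotations, so
    sessions are not a single repeated period.
    """
    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    if sorted(mapping) != [0, 1, 2] or len(set(mapping.values())) != 3:
        raise ValueError("mapping must be a bijection {0,1,2} -> labels")
    rng = np.random.default_rng(seed)
    if seq is not None:
        polys = [None]
        seqs = [np.asarray(seq)]
    else:
        polys = [c for c in product(range(3), repeat=3) if c[-1] != 0 and _full_period(c, 3, 3)]
        seqs = [_lfsr_sequence(p, 3, 3) for p in polys]
    runs = []
    for _ in range(n_runs):
        k = int(rng.integers(len(seqs))) if len(seqs) > 1 else 0
        s = seqs[k]
        if len(s) != 26:
            raise ValueError("sequence period must be 26")
        starts = [
            r
            for r in range(26)
            if s[r % 26] == 0 and s[(r + 1) % 26] == 0
        ]
        rot = starts[int(rng.integers(len(starts)))]
        rotated = np.roll(s, -rot)
        labels = tuple(mapping[int(x)] for x in rotated)
        runs.append(
            RunSchedule(
                labels=labels,
                mapping=mapping,
                rotation=rot,
                polynomial=polys[k] if polys[k] is not None else (),
            )
        )
    return runs


def schedule_table(runs: list[RunSchedule]) -> pd.DataFrame:
    """Flatten run schedules into a (run, trial, label, stimulus) table."""
    rows = [
        {"run": r, "trial": t, "label": lb, "stimulus": CODED_SIZE[lb]}
        for r, sched in enumerate(runs)
        for t, lb in enumerate(sched.labels)
    ]
    return pd.DataFrame(rows)


def simulate_staircase(
    psychometric,
    n_trials: int = 180,
    n_staircases: int = 4,
    levels: np.ndarray | None = None,
    seed: int = 0,
    down_rule: int = 2,
) -> pd.DataFrame:
    """Interleaved one-up-N-down staircases on a discrete level ladder.

    ``psychometric`` maps a level (difficulty value) to P(correct); it must be
    monotone in level.  Half of the staircases start from the easiest (top)
    level, half from the hardest (bottom).  After ``down_rule`` consecutive
    correct responses the level steps down (harder); after one error it steps
    up (easier).  The default one-up-two-down rule converges at
    P(correct) = sqrt(1/2) = 70.7 %; one-up-one-down converges at 50 %.

    Returns a trace with columns ``trial, staircase, level_idx, level,
    correct, reversal``.
    """
    if levels is None:
        levels = np.linspace(0.1, 2.0, 20)
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 2:
        raise ValueError("level ladder must have at least 2 levels")
    rng = np.random.default_rng(seed)
    n_top = len(levels) - 1
    idx = [n_top if k < n_staircases // 2 else 0 for k in range(n_staircases)]
    streak = [0] * n_staircases
    last_dir = [0] * n_staircases
    rows = []
    order = rng.integers(n_staircases, size=n_trials)
    for t in range(n_trials):
        k = int(order[t])
        lev_idx = idx[k]
        lev = levels[lev_idx]
        correct = rng.random() < psychometric(lev)
        move = 0
        if correct:
            streak[k] += 1
            if streak[k] == down_rule:
                move = -1  # harder
                streak[k] = 0
        else:
            streak[k] = 0
            move = +1  # easier
        reversal = move != 0 and last_dir[k] != 0 and move != last_dir[k]
        if move != 0:
            last_dir[k] = move
            idx[k] = int(np.clip(idx[k] + move, 0, len(levels) - 1))
        rows.append(
            {
                "trial": t,
                "staircase": k,
                "level_idx": lev_idx,
                "level": lev,
                "correct": bool(correct),
                "reversal": bool(reversal),
            }
        )
    return pd.DataFrame(rows)


def converged_level(trace: pd.DataFrame, discard_reversals: int = 2) -> float:
    """Average level at the late reversals, pooled across staircases."""
    levs = []
    for _, g in trace.groupby("staircase"):
        rev = g.loc[g["reversal"], "level"].to_numpy()
        if len(rev) > discard_reversals:
            levs.append(rev[discard_reversals:])
    if not levs:
        raise ValueError("no reversals recorded")
    return float(np.mean(np.concatenate(levs)))


def weibull(
    x: np.ndarray,
    scale: float,
    shape: float,
    guess: float = 0.5,
    lapse: float = 0.02,
) -> np.ndarray:
    """P(correct | x) = guess + (1-guess-lapse) * (1 - exp(-(x/scale)**shape))."""
    x = np.asarray(x, dtype=float)
    return guess + (1.0 - guess - lapse) * (1.0 - np.exp(-((x / scale) ** shape)))


def fit_weibull(
    trace: pd.DataFrame, guess: float = 0.5, lapse: float = 0.02
) -> CalibrationResult:
    """ML Weibull fit to a staircase trace; threshold at the 70.7 % point.

    Guess and lapse rates are fixed; scale and shape are fitted by maximising
    the Bernoulli likelihood over the presented levels.  ``delta_hat`` is the
    level at which the fitted curve crosses 0.707.
    """
    x = trace["level"].to_numpy(dtype=float)
    y = trace["correct"].to_numpy(dtype=bool)
    informative = (
        len(np.unique(x[y])) >= 1 and np.any(~y) and len(np.unique(x)) >= 2
    )
    if not informative:
        raise ValueError("trace is non-identifiable (needs both outcomes at >=2 levels)")

    def nll(theta):
        scale, shape = np.exp(theta)
        p = np.clip(weibull(x, scale, shape, guess, lapse), 1e-9, 1 - 1e-9)
        return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

    best = None
    for s0 in (np.median(x), np.mean(x)):
        for sh0 in (1.0, 3.0):
            res = minimize(nll, np.log([max(s0, 1e-3), sh0]), method="Nelder-Mead")
            if best is None or res.fun < best.fun:
                best = res
    scale, shape = np.exp(best.x)
    # invert the fitted curve at P = 0.707
    target = 0.707
    frac = (target - guess) / (1.0 - guess - lapse)
    if not 0 < frac < 1:
        raise ValueError("0.707 point outside the fitted curve's range")
    delta_hat = scale * (-np.log1p(-frac)) ** (1.0 / shape)
    return CalibrationResult(
        delta_hat=float(delta_hat),
        weibull_params=(float(scale), float(shape), guess, lapse),
        staircase_trace=trace,
    )
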