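"""Causal-structure scan over three-node linear-Gaussian networks.

Given candidate brain signals for the boundary (b), the inferred stimulus (s)
and the decision variable (v), every three-node network built from one signal
per variable is scored by BIC.  Each of the three node pairs can carry an
edge in either direction or none, giving 27 edge structures per node
combination; the two fully cyclic orientations admit no valid factorization
under a linear-Gaussian model and are enumerated but left unscored.  A
network is scored as the sum over nodes of the Gaussian log-likelihood of the
node regressed on its parents, with BIC = k ln N - 2 loglik; graphs more than
2 BIC units above the best are flagged as significantly worse.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = ["CausalGraphScore", "enumerate_edge_structures", "bic_network_scan"]

PAIRS = (("b", "v"), ("v", "s"), ("s", "b"))
EDGE_STATES = (1, -1, 0)  # x -> y, x <- y, no edge


@dataclass
class CausalGraphScore:
    nodes: dict[str, int]  # which candidate signal indexed each variable
    edges: dict[tuple[str, str], int]
    bic: float
    delta_bic: float
    cyclic: bool

    @property
    def edge_label(self) -> str:
        sym = {1: "->", -1: "<-", 0: "  "}
        return ", ".join(f"{a}{sym[e]}{b}" for (a, b), e in self.edges.items())


def enumerate_edge_structures() -> list[dict[tuple[str, str], int]]:
    """All 27 assignments of {->, <-, none} to the three node pairs."""
    return [dict(zip(PAIRS, combo)) for combo in product(EDGE_STATES, repeat=3)]


def _parents(edges: dict[tuple[str, str], int]) -> dict[str, list[str]]:
    par: dict[str, list[str]] = {"b": [], "s": [], "v": []}
    for (a, b), e in edges.items():
        if e == 1:
            par[b].append(a)
        elif e == -1:
            par[a].append(b)
    return par


def _is_cyclic(parents: dict[str, list[str]]) -> bool:
    # with one edge max per pair, the only possible cycle visits all 3 nodes
    return all(len(p) == 1 for p in parents.values())


def _node_loglik(y: np.ndarray, X: list[np.ndarray]) -> tuple[float, int]:
    n = y.size
    A = np.column_stack([np.ones(n)] + X)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sigma2 = max(resid @ resid / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return float(ll), A.shape[1] + 1  # coefficients + variance


def bic_network_scan(
    b_signals: list[np.ndarray],
    s_signals: list[np.ndarray],
    v_signals: list[np.ndarray],
    delta_threshold: float = 2.0,
) -> list[CausalGraphScore]:
    """Score all node combinations x 27 edge structures, ranked by BIC.

    Signals must be aligned per-trial series of equal length (>= 10 trials).
    Returns scores sorted ascending by BIC with cyclic structures (BIC = inf)
    last; ``delta_bic`` is relative to the best scored graph.
    """
    lengths = {len(x) for x in b_signals + s_signals + v_signals}
    if len(lengths) != 1:
        raise ValueError("all signals must share the same trial length")
    n = lengths.pop()
    if n < 10:
        raise ValueError("need at least 10 common trials")

    structures = enumerate_edge_structures()
    scores: list[CausalGraphScore] = []
    for ib, is_, iv in product(
        range(len(b_signals)), range(len(s_signals)), range(len(v_signals))
    ):
        sig = {
            "b": np.asarray(b_signals[ib], dtype=float),
            "s": np.asarray(s_signals[is_], dtype=float),
            "v": np.asarray(v_signals[iv], dtype=float),
        }
        for edges in structures:
            parents = _parents(edges)
            cyclic = _is_cyclic(parents)
            if cyclic:
                bic = np.inf
            else:
                ll_tot, k_tot = 0.0, 0
                for node, par in parents.items():
                    ll, k = _node_loglik(sig[node], [sig[p] for p in par])
                    ll_tot += ll
                    k_tot += k
                bic = k_tot * np.log(n) - 2.0 * ll_tot
            scores.append(
                CausalGraphScore(
                    nodes={"b": ib, "s": is_, "v": iv},
                    edges=dict(edges),
                    bic=float(bic),
                    delta_bic=np.nan,
                    cyclic=cyclic,
                )
            )
    best = min(s.bic for s in scores if not s.cyclic)
    for s in scores:
        s.delta_bic = float(s.bic - best)
    scores.sort(key=lambda s: s.bic)
    return scores
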