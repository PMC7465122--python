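"""Independent brute-force oracles used to check the implementation.

Each oracle recomputes a quantity from its definition (loops, exhaustive
enumeration, exact rational arithmetic) without sharing code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap by explicit triple loop."""
    n = a.shape[0]
    k = a.sum(axis=1)
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            omega[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return omega


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by its definition: min over the tail of p * m / rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for pos, idx in enumerate(order, start=1):
        tail = [p[order[k]] * m / (k + 1) for k in range(pos - 1, m)]
        adjusted[idx] = min(1.0, min(tail))
    return adjusted


def hypergeom_upper_tail(M: int, K: int, n: int, x: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(M, K, n), rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(max(x, 0), min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(min(total, Fraction(1)))


def km_oracle(times: np.ndarray, events: np.ndarray) -> list[tuple[float, float]]:
    """Product-limit estimate as explicit risk-set products at event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    curve = []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - deaths / at_risk
        curve.append((t, s))
    return curve


def km_median_oracle(times: np.ndarray, events: np.ndarray) -> float:
    """Smallest event time with S(t) <= 0.5; NaN when never reached."""
    for t, s in km_oracle(times, events):
        if s <= 0.5:
            return t
    return float("nan")


def core_weight_oracle(adj: dict[str, set[str]], v: str, degree_cutoff: int = 2) -> float:
    """MCODE vertex weight by exhaustive subset enumeration.

    The highest k-core of the closed neighborhood is found by scanning all
    vertex subsets for the maximum achievable minimum internal degree; the
    core itself is the union of all maximizing subsets. Only feasible for
    neighborhoods of <= ~15 vertices.
    """
    if len(adj[v]) < degree_cutoff:
        return 0.0
    nodes = sorted(adj[v] | {v})
    best_k = -1
    core: set[str] = set()
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            ss = set(subset)
            mindeg = min(len(adj[u] & ss) for u in ss)
            if mindeg > best_k:
                best_k = mindeg
                core = set(ss)
            elif mindeg == best_k:
                core |= ss
    n = len(core)
    if n < 2:
        return 0.0
    e = sum(1 for a, b in itertools.combinations(sorted(core), 2) if b in adj[a])
    density = 2.0 * e / (n * (n - 1))
    return best_k * density


def ffl_triples_oracle(edges: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """All closed (miRNA, TF, gene) triples by triple loop over role sets."""
    eset = set(edges)
    mirnas = {s for s, _, t in edges if t.startswith("miRNA")}
    tfs = {d for _, d, t in edges if t == "miRNA-TF"} | {s for s, _, t in edges if t == "TF-gene"}
    genes = {d for _, d, t in edges if t.endswith("gene") and t != "TF-gene"}
    genes |= {d for _, d, t in edges if t == "TF-gene"}
    out = []
    for m in sorted(mirnas):
        for tf in sorted(tfs):
            for g in sorted(genes):
                if (
                    (m, tf, "miRNA-TF") in eset
                    and (tf, g, "TF-gene") in eset
                    and (m, g, "miRNA-gene") in eset
                ):
                    out.append((m, tf, g))
    return out


def logrank_oracle(times, events, groups) -> float:
    """Log-rank chi-square from the textbook 2x2 table at each event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        n1 = int(((times >= t) & (groups == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (groups == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0
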