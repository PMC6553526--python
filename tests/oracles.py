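"""Brute-force oracles, independent of the package implementation.

Everything here is exhaustive enumeration or a closed form over math.comb —
usable only at tiny sizes, which is the point.
"""

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_upper_tail_enum(pop: int, n_a: int, n_b: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(pop, n_b) draws. pop <= ~12."""
    marked = set(range(n_a))
    hits = sum(
        1 for draw in combinations(range(pop), n_b) if len(marked & set(draw)) >= k
    )
    return hits / comb(pop, n_b)


def hypergeom_upper_tail_closed(pop: int, n_a: int, n_b: int, k: int) -> float:
    """Closed-form upper tail via math.comb (for larger toy populations)."""
    total = comb(pop, n_b)
    return sum(
        comb(n_a, i) * comb(pop - n_a, n_b - i) for i in range(k, min(n_a, n_b) + 1)
    ) / total


def _avg_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_sum_enum(a, b, alternative="two-sided"):
    """Exact rank-sum (statistic, p) by enumerating all group assignments."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = _avg_ranks(pooled)
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), na)])
    mean_w = ws.mean()
    eps = 1e-9
    if alternative == "greater":
        p = np.mean(ws >= w_obs - eps)
    elif alternative == "less":
        p = np.mean(ws <= w_obs + eps)
    else:
        p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - eps)
    return float(w_obs), float(p)


def spearman_via_pearson_on_ranks(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx = _avg_ranks(np.asarray(x, float))
    ry = _avg_ranks(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
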