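"""Statistical primitives: rank correlation, rank-sum test, hypergeometric
overlap p, and empirical permutation p-values.

The empirical p is the raw Monte-Carlo tail count ``k / n_perm`` (not the
add-one variant), so a statistic more extreme than every permutation is
reported as the bound ``< 1/n_perm`` — e.g. "< 0.0001" at 10,000 draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class EmpiricalP:
    """Empirical permutation p-value as a tail count over n_perm draws."""

    k: int
    n_perm: int
    tail: str  # "ge" or "le"

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n_perm):
            raise ValueError("need 0 <= k <= n_perm")
        if self.tail not in ("ge", "le"):
            raise ValueError("tail must be 'ge' or 'le'")

    @property
    def p(self) -> float:
        return self.k / self.n_perm

    @property
    def p_report(self) -> str:
        """Printable p; a zero count is an upper bound, not an exact zero."""
        if self.k == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p:g}"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises on length mismatch, length < 2, or a constant input (the
    correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman rho is undefined for a constant sequence")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def _rank_sum_exact(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact rank-sum p by enumerating all C(n, |a|) group assignments.

    Average ranks make this valid under ties; feasible for small n only.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = len(pooled), len(a)
    w_obs = float(ranks[:na].sum())
    ws = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(n), na)], dtype=float
    )
    mean_w = ws.mean()
    eps = 1e-9
    if alternative == "greater":
        p = np.mean(ws >= w_obs - eps)
    elif alternative == "less":
        p = np.mean(ws <= w_obs + eps)
    else:
        p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - eps)
    return w_obs, float(p)


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (rank sum of ``a``, p).

    ``method='auto'`` enumerates all group assignments exactly when the
    pooled size is <= 12 (valid under ties) and otherwise uses the
    tie-corrected normal approximation without continuity correction.
    ``'exact'`` forces exact computation (scipy's no-ties enumeration for
    larger samples); ``'normal'`` forces the approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n = len(a) + len(b)
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto|exact|normal")
    if method == "auto":
        method = "exact" if n <= 12 else "normal"
    if method == "exact":
        if n <= 12 or len(np.unique(np.concatenate([a, b]))) < n:
            return _rank_sum_exact(a, b, alternative)
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=False
        )
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank sum of a
    return w, float(res.pvalue)


def hypergeom_overlap_p(pop: int, n_a: int, n_b: int, k: int) -> float:
    """Upper-tail P(X >= k) that a size-``n_b`` draw from ``pop`` elements,
    ``n_a`` of which are marked, contains at least ``k`` marked ones."""
    if not (0 <= n_a <= pop and 0 <= n_b <= pop):
        raise ValueError("need 0 <= n_a, n_b <= pop")
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError("need 0 <= k <= min(n_a, n_b)")
    return float(sps.hypergeom.sf(k - 1, pop, n_a, n_b))


def empirical_p(
    observed: float, permuted: Sequence[float], tail: str = "ge"
) -> EmpiricalP:
    """Tail count of permuted statistics at least (``ge``) / at most (``le``)
    as extreme as the observed one; ties count toward the tail."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted sequence must be non-empty")
    if tail == "ge":
        k = int(np.sum(permuted >= observed))
    elif tail == "le":
        k = int(np.sum(permuted <= observed))
    else:
        raise ValueError("tail must be 'ge' or 'le'")
    return EmpiricalP(k=k, n_perm=int(permuted.size), tail=tail)
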