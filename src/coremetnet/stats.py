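"""Nonparametric tests used by the comparative analysis.

Four tests, with exact small-sample behaviour where feasible:

* Mann-Whitney U, two-tailed, with a tie-aware exact mode that enumerates
  the permutation null for combined n <= 20 and a normal approximation
  with tie correction otherwise.
* Kruskal-Wallis omnibus with Dunn's pairwise z comparisons
  (Bonferroni-adjusted over all pairs).
* Spearman rank correlation (average ranks for ties); exact permutation
  p-value for n <= 9, t-approximation otherwise.
* Fisher's exact 2x2, two-tailed by the "sum of hypergeometric
  probabilities <= observed" convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    adjusted: bool = False
    extra: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


@lru_cache(maxsize=64)
def _exact_u_distribution(
    n_a: int, midranks: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of U for group sizes (n_a, N-n_a) over the given
    midrank multiset, by full enumeration of C(N, n_a) group assignments.

    Cached on (n_a, midranks): for continuous data the midranks are just
    1..N, so repeated calls (e.g. in simulations) enumerate only once.
    """
    ranks = np.asarray(midranks)
    n = len(ranks)
    offset = n_a * (n_a + 1) / 2
    us = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)),
        dtype=float,
        count=math.comb(n, n_a),
    )
    values, counts = np.unique(us, return_counts=True)
    return values, counts


def mann_whitney(
    group_a: list[float], group_b: list[float], mode: str = "exact"
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    ``mode="exact"`` enumerates the tie-aware permutation null (requires
    combined n <= 20); ``mode="approximate"`` uses the normal approximation
    with tie correction.  If every value is tied across both groups, p = 1
    with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney: all values tied across both groups")
        return TestResult(
            method=f"mann-whitney-{mode}",
            statistic=a.size * b.size / 2,
            p_value=1.0,
            n=(a.size, b.size),
        )
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[: a.size], a.size, b.size)
    m = a.size * b.size

    if mode == "exact":
        if a.size + b.size > 20:
            raise ValueError(
                "exact mode enumerates the permutation null and is limited "
                "to combined n <= 20; use mode='approximate'"
            )
        values, counts = _exact_u_distribution(a.size, tuple(ranks))
        total = counts.sum()
        # two-tailed via the symmetry of U about m/2 under permutation
        u_low = min(u_obs, m - u_obs)
        p = (
            counts[values <= u_low + 1e-9].sum()
            + counts[values >= m - u_low - 1e-9].sum()
        ) / total
        p = min(1.0, float(p))
    elif mode == "approximate":
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'approximate'")
    return TestResult(
        method=f"mann-whitney-{mode}",
        statistic=u_obs,
        p_value=p,
        n=(a.size, b.size),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis_dunn(
    groups: list[list[float]],
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus H test plus Dunn's pairwise comparisons.

    Dunn's z uses the pooled mean-rank difference with tie correction;
    pairwise two-sided p-values are Bonferroni-multiplied by the number of
    pairs (capped at 1) and flagged ``adjusted=True``.
    """
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_dunn requires >= 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        omnibus = TestResult("kruskal-wallis", 0.0, 1.0, tuple(len(g) for g in groups))
        return omnibus, []
    h, p = sps.kruskal(*arrays)
    omnibus = TestResult(
        method="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        n=tuple(a.size for a in arrays),
    )

    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    k = len(arrays)
    n_pairs = k * (k - 1) // 2
    pairwise: list[TestResult] = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12 - tie_term)
            * (1 / arrays[i].size + 1 / arrays[j].size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_pair = min(1.0, 2 * sps.norm.sf(abs(z)) * n_pairs)
        pairwise.append(
            TestResult(
                method=f"dunn[{i}-{j}]",
                statistic=float(z),
                p_value=float(p_pair),
                n=(arrays[i].size, arrays[j].size),
                adjusted=True,
            )
        )
    return omnibus, pairwise


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman_corr(x: list[float], y: list[float], exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with two-sided p-value.

    rho is the Pearson correlation of average ranks.  For n <= 9 the
    p-value is by exact permutation (fraction of the n! orderings with
    \\|rho\\| at least the observed); larger samples use the t-approximation.
    A constant vector leaves rho undefined (NaN statistic, NaN p).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 4:
        raise ValueError("spearman_corr requires equal-length samples, n >= 4")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        logger.warning("spearman_corr: constant input, rho undefined")
        return TestResult("spearman", float("nan"), float("nan"), (xa.size,))
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = _rank_pearson(rx, ry)
    n = xa.size
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            total += 1
            if abs(_rank_pearson(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
        method = "spearman-exact"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-15, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
        method = "spearman-t"
    return TestResult(method, float(rho), min(1.0, float(p)), (n,))


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: list[list[int]]) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 contingency table.

    Two-tailed p sums the hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.  A zero
    margin makes the table degenerate: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2 expects a 2x2 table of counts >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact_2x2: zero margin, p = 1")
        return TestResult("fisher-exact", float("nan"), 1.0, tuple(t.sum(axis=1)))
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        n=tuple(int(v) for v in t.sum(axis=1)),
    )


__all__ = [
    "TestResult",
    "mann_whitney",
    "kruskal_wallis_dunn",
    "spearman_corr",
    "fisher_exact_2x2",
]
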