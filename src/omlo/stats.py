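"""Exact and approximate nonparametric tests shared across the toolkit.

The organoid analyses lean on small-sample tests where asymptotic
approximations are unreliable: trend tests on five timepoints, rank-sum
comparisons of three organoids per arm, signed-rank comparisons over ten
images.  This module provides those tests with exact enumeration where the
problem size permits, plus the seeded permutation engine and Bonferroni
adjustment used by the spatial and enrichment analyses.

All results are returned as plain dataclasses that serialise to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TrendResult",
    "ExactTestResult",
    "mann_kendall",
    "rank_sum_exact",
    "signed_rank_exact",
    "fisher_greater",
    "permute_p",
    "bonferroni",
]


@dataclass
class TrendResult:
    """Mann-Kendall trend test outcome.

    ``s`` is the Kendall score (number of concordant minus discordant pairs
    relative to the time order), ``var_s`` its null variance (tie-corrected),
    ``tau`` the rank correlation with time, ``z`` the continuity-corrected
    normal deviate and ``p`` the two-sided p-value.
    """

    n: int
    s: int
    var_s: float
    tau: float
    z: float
    p: float
    method: str = "normal-approximation"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExactTestResult:
    statistic: float
    p: float
    method: Literal["exact-enumeration", "normal-approximation"]
    n: int
    n2: int | None = None
    n_dropped_zeros: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def mann_kendall(x: Sequence[float], exact: bool = False) -> TrendResult:
    """Mann-Kendall trend test on a time-ordered series.

    The score is ``S = sum_{i<j} sign(x_j - x_i)``.  Under no trend,
    ``Var(S) = n(n-1)(2n+5)/18`` minus the usual tie correction, and the
    continuity-corrected deviate ``z = (S - sign(S)) / sqrt(Var(S))`` is
    referred to the standard normal (two-sided).  ``tau`` is Kendall's
    tau-b (tie adjusted denominator).

    The normal approximation with continuity correction is the default for
    every n, mirroring the common R implementation used for timecourse
    proportions; ``exact=True`` switches to full enumeration of the
    permutation distribution of S (untied series only, n <= 10).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"Mann-Kendall requires n >= 3, got n={n}")
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())

    # tie correction over groups of equal values
    _, counts = np.unique(x, return_counts=True)
    tie_term = float((counts * (counts - 1) * (2 * counts + 5)).sum())
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    n_pairs = n * (n - 1) / 2
    tie_pairs = float((counts * (counts - 1) / 2).sum())
    denom = math.sqrt((n_pairs - tie_pairs) * n_pairs)
    tau = s / denom if denom > 0 else 0.0

    if exact:
        if counts.max() > 1:
            raise ValueError("exact Mann-Kendall enumeration requires an untied series")
        if n > 10:
            raise ValueError("exact enumeration limited to n <= 10")
        from itertools import permutations

        abs_s = abs(s)
        total = 0
        extreme = 0
        base = np.arange(n)
        for perm in permutations(range(n)):
            y = np.asarray(perm)
            d = np.sign(y[None, :] - y[:, None])
            sp = int(np.triu(d, k=1)[np.ix_(base, base)].sum())
            total += 1
            if abs(sp) >= abs_s:
                extreme += 1
        p = extreme / total
        z = 0.0
        return TrendResult(n, s, var_s, tau, z, p, method="exact-enumeration")

    if var_s <= 0:
        return TrendResult(n, s, var_s, tau, 0.0, 1.0)
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * _sps.norm.sf(abs(z))
    return TrendResult(n, s, var_s, tau, z, min(1.0, p))


def _rank_sum_counts(n1: int, n: int) -> np.ndarray:
    """Number of n1-subsets of ranks {1..n} attaining each rank-sum.

    Dynamic programme over (subset size, sum); index [k, s] counts k-subsets
    summing to s.  Returns the distribution for subset size n1.
    """
    max_sum = n * (n + 1) // 2
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            table[k, r:] += table[k - 1, : max_sum + 1 - r]
    return table[n1]


def rank_sum_exact(a: Sequence[float], b: Sequence[float]) -> ExactTestResult:
    """Two-sided Wilcoxon rank-sum test, exact when feasible.

    The exact two-sided p is ``2 * min(P(W <= w), P(W >= w))`` capped at 1,
    where W is the rank-sum of group ``a`` under random assignment of pooled
    ranks.  Exact enumeration is used for untied pooled data when
    ``C(n1+n2, n1) <= 1e6``; otherwise the tie-corrected normal approximation
    is reported with its method flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    has_ties = np.unique(pooled).size < n
    if has_ties or math.comb(n, n1) > 1_000_000:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        w = float(_sps.rankdata(pooled)[:n1].sum())
        return ExactTestResult(w, float(res.pvalue), "normal-approximation", n1, n2)

    ranks = _sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    dist = _rank_sum_counts(n1, n)
    total = dist.sum()
    sums = np.arange(dist.size)
    p_le = dist[sums <= w].sum() / total
    p_ge = dist[sums >= w].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return ExactTestResult(w, p, "exact-enumeration", n1, n2)


def signed_rank_exact(diffs: Sequence[float]) -> ExactTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment) and
    reported.  For n <= 25 retained pairs the full 2^n sign-flip
    distribution of ``W+`` (sum of ranks of positive differences, average
    ranks for tied magnitudes) is enumerated; the two-sided p is
    ``2 * min(P(W+ <= w), P(W+ >= w))`` capped at 1.  Larger n falls back to
    the normal approximation.
    """
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    n_dropped = d.size - nz.size
    if nz.size == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return ExactTestResult(0.0, 1.0, "exact-enumeration", 0, None, n_dropped)
    n = nz.size
    ranks = _sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n > 25:
        res = _sps.wilcoxon(nz, alternative="two-sided", method="approx", correction=True)
        return ExactTestResult(w_plus, float(res.pvalue), "normal-approximation", n, None, n_dropped)

    # enumerate W+ over all sign patterns via generating function on doubled
    # ranks (keeps tied half-ranks integral)
    r2 = np.round(ranks * 2).astype(int)
    max_sum = int(r2.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: max_sum + 1 - r]
    total = counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return ExactTestResult(w_plus, p, "exact-enumeration", n, None, n_dropped)


def fisher_greater(k: int, big_k: int, n: int, big_n: int) -> float:
    """One-sided (greater) Fisher exact p-value for a 2x2 table.

    ``k`` successes drawn in a sample of ``n`` from a population of ``big_n``
    containing ``big_k`` successes:
    ``p = sum_{i=k}^{min(big_k, n)} C(big_k, i) C(big_n-big_k, n-i) / C(big_n, n)``.

    Computed with exact integer binomials, so it agrees with enumeration to
    floating-point precision.
    """
    if not (0 <= k <= min(big_k, n) and big_k <= big_n and n <= big_n):
        raise ValueError(f"inconsistent table margins: k={k}, K={big_k}, n={n}, N={big_n}")
    numer = sum(
        math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
        for i in range(k, min(big_k, n) + 1)
    )
    return numer / math.comb(big_n, n)


def permute_p(
    observed: float,
    null_fn: Callable[[np.random.Generator], float],
    n_perm: int = 10_000,
    side: Literal["less", "greater", "two-sided"] = "less",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Seeded permutation p-value with the add-one correction.

    ``null_fn`` draws one null statistic per call from the supplied
    generator.  ``p = (1 + #{null at least as extreme}) / (n_perm + 1)``,
    which never returns 0 and is exact under the permutation null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.array([null_fn(rng) for _ in range(n_perm)], dtype=float)
    if side == "less":
        hits = int((null <= observed).sum())
    elif side == "greater":
        hits = int((null >= observed).sum())
    else:
        centred = np.abs(null - np.median(null))
        hits = int((centred >= abs(observed - np.median(null))).sum())
    return (1 + hits) / (n_perm + 1), null


def bonferroni(ps: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to len(ps)."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = ps.size
    if m < ps.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * ps)
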