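"""Rank-based comparisons of survival distributions.

Survival proportions from packet experiments are bounded, zero-inflated
and rarely normal, so group comparisons use rank statistics: the
Mann-Whitney U (two groups), Kruskal-Wallis H (three or more) with
Dunn's pairwise post-hoc z tests, and a Shapiro-Wilk screen used only to
decide between parametric and rank-based reporting paths.

Conventions recorded in every result: W is the rank-sum of the first
sample minus n_a(n_a+1)/2 (midranks under ties); the exact null
distribution is enumerated for small tie-free samples and a
tie-corrected, continuity-corrected normal approximation is used
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: combined sample size at or below which the exact U distribution is used
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic_name: str
    statistic: float
    p_value: float
    df: float | None = None
    group_sizes: tuple[int, ...] = ()
    ties_present: bool = False
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


def _as_arrays(*samples: Sequence[float]) -> list[np.ndarray]:
    out = []
    for i, s in enumerate(samples):
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError(f"sample {i} is empty")
        out.append(a)
    return out


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    W (the U statistic of ``sample_a``) equals the midrank sum of
    ``sample_a`` minus n_a(n_a+1)/2.  With no ties and a combined size of
    at most ``EXACT_LIMIT`` the p-value enumerates the exact permutation
    distribution; otherwise a normal approximation with tie and
    continuity corrections is used.  Two identical constant samples give
    p = 1 with a ``degenerate`` flag.
    """
    a, b = _as_arrays(sample_a, sample_b)
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size

    if np.all(pooled == pooled[0]):
        w = a.size * b.size / 2.0
        return TestResult(
            method="Mann-Whitney U",
            statistic_name="W",
            statistic=w,
            p_value=1.0,
            group_sizes=(a.size, b.size),
            ties_present=True,
            degenerate=True,
            detail={"convention": "rank-sum minus n_a(n_a+1)/2"},
        )

    exact = (pooled.size <= EXACT_LIMIT) and not ties
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return TestResult(
        method="Mann-Whitney U",
        statistic_name="W",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(a.size, b.size),
        ties_present=ties,
        detail={
            "convention": "rank-sum minus n_a(n_a+1)/2",
            "path": "exact enumeration" if exact
            else "normal approximation, tie and continuity corrected",
        },
    )


def mann_whitney_exact_oracle(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Brute-force two-sided permutation p for the U statistic.

    Enumerates every assignment of the pooled values to the two group
    sizes and counts assignments whose U is at least as extreme (in
    distance from the null mean n_a n_b / 2) as the observed U.  Only
    usable at small n; kept independent of :func:`mann_whitney_u` as a
    verification oracle.
    """
    from itertools import combinations

    a, b = _as_arrays(sample_a, sample_b)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size

    def u_of(idx: tuple[int, ...]) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        ranks = stats.rankdata(pooled)
        return ranks[mask].sum() - n_a * (n_a + 1) / 2.0

    observed = u_of(tuple(range(n_a)))
    mean = n_a * (n - n_a) / 2.0
    count = total = 0
    for idx in combinations(range(n), n_a):
        u = u_of(idx)
        total += 1
        if abs(u - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return observed, count / total


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-squared on k-1 df."""
    arrays = _as_arrays(*groups)
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    pooled = np.concatenate(arrays)
    ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(
            method="Kruskal-Wallis",
            statistic_name="H",
            statistic=0.0,
            p_value=1.0,
            df=len(arrays) - 1,
            group_sizes=tuple(a.size for a in arrays),
            ties_present=True,
            degenerate=True,
        )
    h, p = stats.kruskal(*arrays)
    return TestResult(
        method="Kruskal-Wallis",
        statistic_name="H",
        statistic=float(h),
        p_value=float(p),
        df=len(arrays) - 1,
        group_sizes=tuple(a.size for a in arrays),
        ties_present=ties,
    )


def dunn_posthoc(
    *groups: Sequence[float],
    labels: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> list[TestResult]:
    """Dunn's pairwise z tests on pooled midranks after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the tie term T = sum(t^3 - t) / (12 (N - 1)).  Adjustment is one
    of none / bonferroni / holm and is recorded in every result.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    arrays = _as_arrays(*groups)
    k = len(arrays)
    if k < 2:
        raise ValueError("dunn_posthoc needs at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    zs = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adjusted = _adjust_p(np.array(raw), adjustment)

    results = []
    for (i, j), z, p_raw, p_adj in zip(pairs, zs, raw, adjusted):
        results.append(
            TestResult(
                method="Dunn post-hoc",
                statistic_name="z",
                statistic=float(z),
                p_value=float(p_adj),
                group_sizes=(sizes[i], sizes[j]),
                ties_present=bool(tie_term > 0),
                detail={
                    "comparison": f"{labels[i]} vs {labels[j]}",
                    "p_raw": float(p_raw),
                    "adjustment": adjustment,
                },
            )
        )
    return results


def _adjust_p(raw: np.ndarray, method: str) -> np.ndarray:
    m = raw.size
    if method == "none" or m == 1:
        return np.clip(raw, 0.0, 1.0)
    if method == "bonferroni":
        return np.clip(raw * m, 0.0, 1.0)
    # holm: step-down, enforced monotone in the raw ordering
    order = np.argsort(raw)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def normality_screen(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test, gating parametric vs rank-based paths."""
    a = np.asarray(values, dtype=float)
    if not 3 <= a.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={a.size}")
    if np.all(a == a[0]):
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(a)
    return TestResult(
        method="Shapiro-Wilk",
        statistic_name="W",
        statistic=float(w),
        p_value=float(p),
        group_sizes=(a.size,),
    )
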