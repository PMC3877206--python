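"""Nonparametric group comparisons: Mann-Whitney and Kruskal-Wallis/Dunn.

The two-group test enumerates the exact null distribution of U for small
tie-free samples (combined n <= 20) and falls back to the tie-corrected
normal approximation otherwise. The multi-group path is Kruskal-Wallis
with tie correction followed by pairwise Dunn z-tests with a familywise
(Bonferroni) adjustment, the convention of common "Dunn's post-test"
implementations. Stars: p < 0.05 (*), < 0.01 (**), < 0.001 (***).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupComparison",
    "stars",
    "mann_whitney",
    "kruskal_dunn",
    "exact_u_distribution",
]


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    stars: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p out of [0, 1]")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("each group needs n >= 1")


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@lru_cache(maxsize=64)
def exact_u_distribution(n_a: int, n_b: int) -> tuple[np.ndarray, int]:
    """Exact null distribution of U_A by enumerating all C(n_a+n_b, n_a)
    assignments of ranks to group A (tie-free case).

    Returns (counts over U = 0..n_a*n_b, total count).
    """
    n = n_a + n_b
    counts = np.zeros(n_a * n_b + 1, dtype=np.int64)
    base = n_a * (n_a + 1) // 2
    for combo in itertools.combinations(range(1, n + 1), n_a):
        u = sum(combo) - base  # rank-sum minus minimum = U_A
        counts[u] += 1
    return counts, int(counts.sum())


def _exact_two_sided_p(u_a: float, n_a: int, n_b: int) -> float:
    counts, total = exact_u_distribution(n_a, n_b)
    u = int(round(u_a))
    lower = counts[: u + 1].sum()
    upper = counts[u:].sum()
    return float(min(1.0, 2.0 * min(lower, upper) / total))


def _rank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group A via midranks."""
    combined = np.concatenate([a, b])
    ranks = sstats.rankdata(combined)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(
    group_a,
    group_b,
    mode: str = "auto",
    metric: str = "",
    label_a: str = "A",
    label_b: str = "B",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Two-tailed (by default) Mann-Whitney U test.

    mode: "exact" enumerates the null distribution (requires no ties for
    validity; combined n <= 20 for tractability), "asymptotic" uses the
    tie-corrected normal approximation, "auto" picks exact when small
    and tie-free. When every value in both groups is identical the test
    is degenerate and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group must be non-empty")

    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        u = len(a) * len(b) / 2.0
        return GroupComparison(
            metric=metric, group_a=label_a, group_b=label_b,
            n_a=len(a), n_b=len(b), test="mann-whitney",
            statistic=u, p_value=1.0, stars="",
        )

    has_ties = len(np.unique(combined)) < len(combined)
    small = len(a) + len(b) <= 20
    if mode == "auto":
        mode = "exact" if (small and not has_ties) else "asymptotic"
    if mode == "exact" and has_ties:
        mode = "asymptotic"  # midrank U has no exact tie-free distribution

    u_a = _rank_u(a, b)
    if mode == "exact":
        if alternative == "two-sided":
            p = _exact_two_sided_p(u_a, len(a), len(b))
        else:
            counts, total = exact_u_distribution(len(a), len(b))
            u = int(round(u_a))
            if alternative == "less":  # A shifted below B -> small U_A
                p = float(counts[: u + 1].sum() / total)
            elif alternative == "greater":
                p = float(counts[u:].sum() / total)
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
    else:
        res = sstats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return GroupComparison(
        metric=metric, group_a=label_a, group_b=label_b,
        n_a=len(a), n_b=len(b), test=f"mann-whitney-{mode}",
        statistic=u_a, p_value=p, stars=stars(p),
    )


def _kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = sstats.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_dunn(
    groups: list,
    labels: list[str] | None = None,
    metric: str = "",
) -> tuple[GroupComparison, list[GroupComparison]]:
    """Kruskal-Wallis followed by Dunn's pairwise post-test.

    Returns the overall comparison (H statistic, chi-square p) and one
    GroupComparison per pair with Bonferroni-adjusted p. Dunn z uses the
    tie-corrected pooled rank variance.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    labels = labels or [f"g{i}" for i in range(len(arrays))]

    all_vals = np.concatenate(arrays)
    n = len(all_vals)
    degenerate = bool(np.all(all_vals == all_vals[0]))
    if degenerate:
        h, p_overall = 0.0, 1.0
    else:
        h = _kruskal_h(arrays)
        p_overall = float(sstats.chi2.sf(h, df=len(arrays) - 1))
    overall = GroupComparison(
        metric=metric, group_a="all", group_b="all",
        n_a=min(len(g) for g in arrays), n_b=max(len(g) for g in arrays),
        test="kruskal-wallis", statistic=h, p_value=p_overall,
        stars=stars(p_overall),
    )

    ranks = sstats.rankdata(all_vals)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0

    m = len(arrays) * (len(arrays) - 1) // 2
    pairwise: list[GroupComparison] = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(arrays), 2):
        if degenerate or var_base <= 0:
            z, p = 0.0, 1.0
        else:
            se = math.sqrt(var_base * (1.0 / len(gi) + 1.0 / len(gj)))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sstats.norm.sf(abs(z)))
        adj = float(min(1.0, p * m))
        pairwise.append(
            GroupComparison(
                metric=metric, group_a=labels[i], group_b=labels[j],
                n_a=len(gi), n_b=len(gj), test="dunn",
                statistic=z, p_value=p, adjusted_p=adj, stars=stars(adj),
            )
        )
    return overall, pairwise
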