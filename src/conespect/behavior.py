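"""Behavioral and mosaic statistics from printed counts and summaries.

Covers the supporting statistics of the phenotype screen: Fisher's exact
test on 2×2 optomotor plate-region counts, two-sample t tests reconstructed
from group means ± SE (chimera cone-count sections), Mann-Whitney U for
optokinetic eye-movement counts (heavily tied small integers, so the exact
tie-aware null distribution is built by dynamic programming), and classical
one-way ANOVA with Tukey HSD pairs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "fisher_exact_2x2",
    "summary_t_test",
    "mann_whitney_u",
    "one_way_anova",
    "TTestResult",
    "MannWhitneyResult",
    "AnovaTable",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Larval counts in plate regions before/after a drifting-grating stimulus.

    Rows are conditions (before, after); columns are plate regions
    (regions 1+2 vs region 3, the rim the stimulus drives larvae toward).
    """

    before_regions_1_2: int
    before_region_3: int
    after_regions_1_2: int
    after_region_3: int

    def __post_init__(self) -> None:
        for v in self.counts.ravel():
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [
                [self.before_regions_1_2, self.before_region_3],
                [self.after_regions_1_2, self.after_region_3],
            ]
        )

    @property
    def n_per_condition(self) -> tuple[int, int]:
        c = self.counts
        return int(c[0].sum()), int(c[1].sum())


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SE summary of one group of n measurements."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n < 2:
            raise ValueError("need n >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str


@dataclass(frozen=True)
class AnovaTable:
    F: float
    df1: int
    df2: int
    p: float
    tukey: tuple  # (i, j, statistic, p) per group pair


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the sum-of-smaller-probabilities convention: add up the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's.  Degenerate
    margins (an empty row or column) give p = 1 with a warning.
    """
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        warnings.warn("empty margin: Fisher exact p is 1 by convention", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(c, alternative="two-sided")
    return float(p)


def summary_t_test(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Two-sample t test reconstructed from group means ± SE.

    t = (mean_b − mean_a)/√(se_a² + se_b²) with df = n_a + n_b − 2; for
    equal group sizes this coincides with the pooled equal-variance t test.
    """
    t = (b.mean - a.mean) / float(np.hypot(a.se, b.se))
    df = a.n + b.n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=int(df), p=min(p, 1.0))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_u_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p for U under exchangeability, ties included.

    Builds the null distribution of the rank sum over all C(n, nx) group
    assignments by dynamic programming over doubled midranks (integers even
    with .5 ties).  Under label exchange U is symmetric about nx·ny/2, so
    the two-sided p sums assignments at least as far from the centre.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    d = np.rint(2.0 * _midranks(pooled)).astype(int)  # doubled midranks
    total = d.sum()
    # counts[k, s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((nx + 1, total + 1))
    counts[0, 0] = 1.0
    for r in d:
        for k in range(nx, 0, -1):  # downward so each item is used once
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[nx]  # over doubled rank sums of the x group
    sums = np.arange(total + 1)
    u_all = sums / 2.0 - nx * (nx + 1) / 2.0  # U for each doubled rank sum
    centre = nx * ny / 2.0
    extreme = np.abs(u_all - centre) >= abs(u_obs - centre) - 1e-9
    return float(dist[extreme].sum() / dist.sum())


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Mann-Whitney U with midrank ties.

    ``method`` 'exact' enumerates the tie-aware null distribution (default
    for groups of ≤ 20), 'asymptotic' uses the normal approximation with
    tie-corrected variance (default above 20).  Returns U for the first
    sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    nx, ny = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    rank_sum_x = float(ranks[:nx].sum())
    u = rank_sum_x - nx * (nx + 1) / 2.0

    if method == "auto":
        method = "exact" if max(nx, ny) <= 20 else "asymptotic"
    if method == "exact":
        p = _exact_u_p(x, y, u)
    elif method == "asymptotic":
        mu = nx * ny / 2.0
        n = nx + ny
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (u - mu) / np.sqrt(var)
            p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MannWhitneyResult(U=float(u), p=min(p, 1.0), method=method)


def one_way_anova(groups: list) -> AnovaTable:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least two groups with n >= 2 each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaTable(F=0.0, df1=df1, df2=df2, p=1.0, tukey=())
        raise ValueError("degenerate within-group variance")
    F, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs = tuple(
        (i, j, float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]))
        for i, j in combinations(range(len(arrays)), 2)
    )
    return AnovaTable(F=float(F), df1=df1, df2=df2, p=float(p), tukey=pairs)
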