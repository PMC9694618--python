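"""Group summary statistics and the two-group Wilcoxon-Mann-Whitney test.

``summarize`` produces the N/mean/median/SD/Q1/Q3 row used to describe each
biomarker per group; ``rank_sum_test`` compares the infection and
no-infection groups without distributional assumptions. For small pooled
samples the test p-value is exact — enumerated over every assignment of the
pooled (mid)ranks to groups, which remains valid under ties — otherwise the
normal approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

#: Pooled-size threshold below which the exact enumeration is used.
EXACT_MAX_POOLED = 12

#: Conventional significance threshold, reported alongside p-values.
ALPHA = 0.05


@dataclass(frozen=True)
class SummaryRow:
    """One descriptive-statistics row: a biomarker (or index) in one group."""

    name: str
    group: str  # "total", "infection" or "no_infection"
    n: int
    mean: float
    median: float
    sd: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U comparison of two groups (two-sided)."""

    statistic: float  # U of the first group, midranks for ties
    p_value: float
    method: Literal["exact", "normal_approx"]
    n1: int
    n2: int


def summarize(values: Sequence[float], name: str, group: str) -> SummaryRow:
    """Descriptive row for one set of values.

    Mean is arithmetic; median uses the midpoint convention for even n;
    SD uses the n-1 denominator (0 for a single value); quartiles use
    linear interpolation of order statistics (quantile p at position
    1+(n-1)p), the common default in scientific software.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryRow(
        name=name,
        group=group,
        n=int(arr.size),
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        sd=sd,
        q1=float(np.quantile(arr, 0.25, method="linear")),
        q3=float(np.quantile(arr, 0.75, method="linear")),
    )


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """U statistic of ``group_a``: #{a > b} + 0.5 * #{a == b} over all pairs.

    Computed via midranks, so ties contribute half wins.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    ranks = sps.rankdata(np.concatenate([a, b]))
    w_a = float(ranks[: a.size].sum())
    return w_a - a.size * (a.size + 1) / 2.0


def _exact_p_two_sided(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every group-1 subset of the pool.

    The permutation distribution of U is symmetric about n1*n2/2 even with
    ties (negating the pooled values maps U to n1*n2 - U over the same set
    of assignments), so the two-sided p counts assignments at least as far
    from the centre as the observed U.
    """
    n = pooled.size
    n2 = n - n1
    ranks = sps.rankdata(pooled)
    centre = n1 * n2 / 2.0
    dev_obs = abs(u_obs - centre)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        # U is a multiple of 0.5; 1e-9 guards float noise in rank sums
        if abs(u - centre) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    force_approx: bool = False,
) -> RankTestResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration when ``n1 + n2 <= 12`` (unless ``force_approx``),
    otherwise a normal approximation with tie correction and continuity
    correction. The returned p is capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = mann_whitney_u(a, b)
    if a.size + b.size <= EXACT_MAX_POOLED and not force_approx:
        p = _exact_p_two_sided(np.concatenate([a, b]), a.size, u)
        method: Literal["exact", "normal_approx"] = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return RankTestResult(
        statistic=u,
        p_value=min(p, 1.0),
        method=method,
        n1=int(a.size),
        n2=int(b.size),
    )
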