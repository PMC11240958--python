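"""Non-parametric k-sample tests of descriptor differences across
communities.

Three complementary tests per descriptor:

* Kruskal-Wallis — rank-based test of location differences (chi-square
  approximation with tie correction, k-1 dof);
* Conover squared-ranks — test of variance (scale) differences: rank the
  absolute deviations from each group's mean, compare sums of squared
  ranks;
* Gehan — generalized Wilcoxon score test from the log-rank family,
  applied to fully observed descriptor values (no censoring): each
  observation scores (#beaten - #beaten by), and the k-group chi-square
  form compares group score sums.

All three report a statistic, k-1 degrees of freedom and a chi-square
p-value; raw p-values are reported (no multiplicity correction by
default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .communities import Partition
from .io import DESCRIPTOR_COLUMNS, DescriptorTable

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One test applied to one descriptor for one partition."""

    method: str  # kruskal_wallis | conover | gehan
    statistic: float
    dof: int
    p_value: float
    descriptor: str = ""
    partition: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GroupTestReport:
    """Battery of test results for one (descriptor table, partition) pair."""

    results: list[TestResult] = field(default_factory=list)
    skipped_reason: Optional[str] = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"descriptor": r.descriptor, "method": r.method,
             "statistic": r.statistic, "dof": r.dof, "p_value": r.p_value}
            for r in self.results
        ])


def _prepare_groups(
    values: np.ndarray,
    groups: np.ndarray,
    min_group_size: int,
) -> list[np.ndarray]:
    """Split values by group label, dropping groups below the size floor."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and group labels must align")
    out = []
    for lab in np.unique(groups):
        x = values[groups == lab]
        if x.size < min_group_size:
            warnings.warn(
                f"dropping group {lab!r} with {x.size} < {min_group_size} observations")
            continue
        out.append(x)
    return out


def _degenerate(method: str, k: int) -> TestResult:
    warnings.warn(f"{method}: all values identical; statistic 0, p = 1")
    return TestResult(method=method, statistic=0.0, dof=max(k - 1, 1), p_value=1.0)


def kruskal_wallis_test(
    values: np.ndarray,
    groups: np.ndarray,
    min_group_size: int = 2,
) -> TestResult:
    """Rank-based k-sample location test (tie-corrected H, chi-square p)."""
    samples = _prepare_groups(values, groups, min_group_size)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    k = len(samples)
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return _degenerate("kruskal_wallis", k)
    stat, p = scipy.stats.kruskal(*samples)
    return TestResult(method="kruskal_wallis", statistic=float(stat),
                      dof=k - 1, p_value=float(p))


def conover_squared_ranks_test(
    values: np.ndarray,
    groups: np.ndarray,
    min_group_size: int = 2,
) -> TestResult:
    """Conover's squared-ranks test of equal variances.

    u_ij = |x_ij - mean_i| are ranked over the pooled sample (midranks for
    ties); with S_i the sum of squared ranks in group i,

        T = [sum_i S_i^2 / n_i - N Sbar^2] / D^2,
        Sbar = mean squared rank,  D^2 = [sum R^4 - N Sbar^2] / (N - 1),

    compared to chi-square with k-1 dof.  Location shifts of any single
    group leave the statistic unchanged.
    """
    samples = _prepare_groups(values, groups, min_group_size)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    k = len(samples)
    u = [np.abs(x - x.mean()) for x in samples]
    pooled = np.concatenate(u)
    N = pooled.size
    if np.ptp(pooled) == 0:
        return _degenerate("conover", k)
    ranks = scipy.stats.rankdata(pooled)
    sq = ranks ** 2
    sbar = sq.mean()
    d2 = (np.sum(sq ** 2) - N * sbar ** 2) / (N - 1)
    if d2 == 0:
        return _degenerate("conover", k)
    sizes = np.array([x.size for x in samples])
    bounds = np.cumsum(sizes)[:-1]
    s_i = np.array([g.sum() for g in np.split(sq, bounds)])
    stat = float((np.sum(s_i ** 2 / sizes) - N * sbar ** 2) / d2)
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, k - 1))
    return TestResult(method="conover", statistic=stat, dof=k - 1, p_value=p)


def gehan_scores(pooled: np.ndarray) -> np.ndarray:
    """U_i = #{j: x_i > x_j} - #{j: x_i < x_j} over the pooled sample."""
    pooled = np.asarray(pooled, dtype=float)
    order = np.sort(pooled)
    less = np.searchsorted(order, pooled, side="left")
    greater = pooled.size - np.searchsorted(order, pooled, side="right")
    return (less - greater).astype(float)


def gehan_test(
    values: np.ndarray,
    groups: np.ndarray,
    min_group_size: int = 2,
) -> TestResult:
    """Gehan generalized Wilcoxon k-sample test (uncensored observations).

    With G_i the sum of Gehan scores in group i of size n_i and U the
    pooled scores,

        statistic = (N - 1) * sum_i G_i^2 / n_i / sum_j U_j^2,

    compared to chi-square with k-1 dof.  The pooled scores always sum to
    zero by antisymmetry.
    """
    samples = _prepare_groups(values, groups, min_group_size)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    k = len(samples)
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return _degenerate("gehan", k)
    scores = gehan_scores(pooled)
    sizes = np.array([x.size for x in samples])
    bounds = np.cumsum(sizes)[:-1]
    g_i = np.array([grp.sum() for grp in np.split(scores, bounds)])
    denom = float(np.sum(scores ** 2))
    if denom == 0:
        return _degenerate("gehan", k)
    stat = float((pooled.size - 1) * np.sum(g_i ** 2 / sizes) / denom)
    p = float(scipy.stats.chi2.sf(stat, k - 1))
    return TestResult(method="gehan", statistic=stat, dof=k - 1, p_value=p)


_TESTS = {
    "kruskal_wallis": kruskal_wallis_test,
    "conover": conover_squared_ranks_test,
    "gehan": gehan_test,
}


def community_descriptor_tests(
    table: DescriptorTable,
    p: Partition,
    partition_name: str = "",
    min_group_size: int = 2,
    bh_correct: bool = False,
) -> GroupTestReport:
    """All 12 descriptors x 3 tests for one community partition.

    A single-community partition yields an empty report with an explicit
    skip marker (group tests are meaningless with one group).  With
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted across
    the battery; by default raw p-values are reported.
    """
    if list(table.ids) != list(p.ids):
        raise ValueError("partition does not cover the descriptor table's ids")
    if p.n_communities < 2:
        return GroupTestReport(
            skipped_reason="only one community: k-sample tests not available")
    sizes = np.bincount(p.labels)
    if int((sizes >= min_group_size).sum()) < 2:
        return GroupTestReport(
            skipped_reason="fewer than two communities meet the size floor")
    report = GroupTestReport()
    for col_idx, descriptor in enumerate(DESCRIPTOR_COLUMNS):
        col = table.values[:, col_idx]
        for method, func in _TESTS.items():
            res = func(col, p.labels, min_group_size=min_group_size)
            res.descriptor = descriptor
            res.partition = partition_name
            report.results.append(res)
    if bh_correct and report.results:
        pvals = np.array([r.p_value for r in report.results])
        adjusted = _benjamini_hochberg(pvals)
        for r, q in zip(report.results, adjusted):
            r.p_value = float(q)
    return report


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
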