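"""Partition-agreement metrics from a shared contingency table.

For partitions P1 (r blocks) and P2 (s blocks) of the same n nodes, the
contingency table n_ij = |block_i(P1) ∩ block_j(P2)| underlies all five
metrics:

* VOI  = H(P1) + H(P2) - 2 I(P1;P2)         (nats; 0 iff identical)
* NMI  = 2 I / (H(P1) + H(P2))              (in [0, 1]; base-free)
* SJD  = [n - sum_i max_j n_ij] + [n - sum_j max_i n_ij]   (van Dongen)
* RI   = (c1 + c2) / C(n, 2)                (pair agreement rate)
* ARI  = chance-corrected RI
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .communities import Partition


@dataclass
class ContingencyTable:
    """r x s block-intersection counts with marginals."""

    counts: np.ndarray  # (r, s) integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ComparisonResult:
    """The five agreement metrics for one pair of partitions."""

    voi: float
    nmi: float
    sjd: int
    ri: float
    ari: float
    entropy_base: str = "nats"

    def to_dict(self) -> dict:
        return {"VOI": self.voi, "NMI": self.nmi, "SJD": self.sjd,
                "RI": self.ri, "ARI": self.ari, "entropy_base": self.entropy_base}


def _check_pair(p1: Partition, p2: Partition) -> None:
    if list(p1.ids) != list(p2.ids):
        diff = set(p1.ids) ^ set(p2.ids)
        raise ValueError(f"partitions cover different node sets: {sorted(diff)!r}")


def build_contingency(p1: Partition, p2: Partition) -> ContingencyTable:
    """Block-intersection counts; marginals equal the block sizes."""
    _check_pair(p1, p2)
    r, s = p1.n_communities, p2.n_communities
    counts = np.zeros((r, s), dtype=np.int64)
    np.add.at(counts, (p1.labels, p2.labels), 1)
    return ContingencyTable(counts=counts)


def _entropies(table: ContingencyTable) -> tuple[float, float, float]:
    """(H(P1), H(P2), I(P1;P2)) in nats from the contingency counts."""
    n = table.n
    a = table.row_sums / n
    b = table.col_sums / n
    h1 = float(-(a[a > 0] * np.log(a[a > 0])).sum())
    h2 = float(-(b[b > 0] * np.log(b[b > 0])).sum())
    p = table.counts / n
    nz = p > 0
    outer = np.outer(a, b)
    mi = float((p[nz] * np.log(p[nz] / outer[nz])).sum())
    return h1, h2, max(mi, 0.0)


def variation_of_information(p1: Partition, p2: Partition) -> float:
    """VOI = H(P1) + H(P2) - 2 I, in nats; symmetric, 0 iff identical."""
    _check_pair(p1, p2)
    if np.array_equal(p1.labels, p2.labels):
        return 0.0  # exact, avoiding float residue in H + H - 2I
    h1, h2, mi = _entropies(build_contingency(p1, p2))
    return max(h1 + h2 - 2.0 * mi, 0.0)


def normalized_mutual_information(p1: Partition, p2: Partition) -> float:
    """NMI = 2 I / (H(P1) + H(P2)).

    Two single-block partitions (both entropies 0) compare as 1 by
    convention; if exactly one entropy is 0, mutual information is 0 and
    so is the NMI.
    """
    h1, h2, mi = _entropies(build_contingency(p1, p2))
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    return min(2.0 * mi / (h1 + h2), 1.0)


def split_join_distance(p1: Partition, p2: Partition) -> int:
    """van Dongen split-join distance, in [0, 2n]; 0 iff identical."""
    table = build_contingency(p1, p2)
    n = table.n
    s12 = n - int(table.counts.max(axis=1).sum())
    s21 = n - int(table.counts.max(axis=0).sum())
    return s12 + s21


def _pair_counts(table: ContingencyTable) -> tuple[int, int, int, int]:
    """(c1, c2, sum_C(a,2), sum_C(b,2)): agreeing pair counts and marginals."""
    def comb2(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    c1 = comb2(table.counts.ravel())
    sum_a = comb2(table.row_sums)
    sum_b = comb2(table.col_sums)
    total = math.comb(table.n, 2)
    c2 = total - sum_a - sum_b + c1
    return c1, c2, sum_a, sum_b


def rand_index(p1: Partition, p2: Partition) -> float:
    """RI = (c1 + c2) / C(n, 2): fraction of pairs treated consistently."""
    table = build_contingency(p1, p2)
    if table.n < 2:
        raise ValueError("Rand index needs at least 2 nodes")
    c1, c2, _, _ = _pair_counts(table)
    return (c1 + c2) / math.comb(table.n, 2)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Chance-corrected Rand index.

    ARI = (c1 - E) / (max - E) with E = sum_C(a,2) sum_C(b,2) / C(n,2)
    and max = [sum_C(a,2) + sum_C(b,2)] / 2.  The denominator degenerates
    only when both partitions are all-singletons or both single-block —
    i.e. when they are identical — and then 1 is returned with a warning.
    """
    table = build_contingency(p1, p2)
    if table.n < 2:
        raise ValueError("adjusted Rand index needs at least 2 nodes")
    c1, _, sum_a, sum_b = _pair_counts(table)
    total = math.comb(table.n, 2)
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    denom = maximum - expected
    if denom == 0:
        identical = np.array_equal(p1.labels, p2.labels)
        warnings.warn("degenerate ARI denominator; returning exact-match indicator")
        return 1.0 if identical else 0.0
    return float((c1 - expected) / denom)


def compare_partitions(p1: Partition, p2: Partition) -> ComparisonResult:
    """All five agreement metrics for one pair of partitions."""
    return ComparisonResult(
        voi=variation_of_information(p1, p2),
        nmi=normalized_mutual_information(p1, p2),
        sjd=split_join_distance(p1, p2),
        ri=rand_index(p1, p2),
        ari=adjusted_rand_index(p1, p2),
    )
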