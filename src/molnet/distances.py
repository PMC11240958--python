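"""The four pairwise inter-molecule distance matrices.

* Euclidean distance between (optionally z-scored) 12-descriptor vectors,
  d(A,B) = sqrt(sum_k (a_k - b_k)^2).
* Tanimoto distance on binary fingerprints, d = 1 - T with
  T = A.B / (|A|^2 + |B|^2 - A.B).
* Hamming distance on binary fingerprints, d = sum_i |a_i - b_i|.
* Levenshtein (unit-cost edit) distance on SMILES strings.

All matrices are symmetric with zero diagonal and non-negative entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_NAMES = ("euclidean", "tanimoto", "hamming", "levenshtein")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix for one metric."""

    ids: Sequence[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValueError("negative distance")
        if self.metric_name == "tanimoto" and (self.values > 1 + 1e-12).any():
            raise ValueError("tanimoto distance > 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str, metric_name: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float),
                   metric_name=metric_name)

    def to_npz(self, path: str) -> None:
        np.savez_compressed(path, values=self.values,
                            ids=np.array(list(self.ids), dtype=object),
                            metric_name=self.metric_name)

    @classmethod
    def from_npz(cls, path: str) -> "DistanceMatrix":
        data = np.load(path, allow_pickle=True)
        return cls(ids=list(data["ids"]), values=data["values"],
                   metric_name=str(data["metric_name"]))


def euclidean_matrix(table, scaling: str = "zscore") -> DistanceMatrix:
    """Euclidean distances between descriptor rows.

    With ``scaling='zscore'`` each column is standardised to mean 0 / sd 1
    first, so no single descriptor's units dominate; constant columns are
    dropped with a warning (their contribution would be zero anyway after
    centering, but they make the sd undefined).
    """
    X = np.asarray(table.values, dtype=float)
    ids = list(table.ids)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite descriptor value")
    if scaling == "zscore":
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d constant descriptor column(s) before z-scoring",
                           int((~keep).sum()))
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, values=d, metric_name="euclidean")


def _check_fps(fps: np.ndarray) -> np.ndarray:
    fps = np.asarray(fps)
    if fps.ndim != 2:
        raise ValueError("fingerprints must be an (n, L) matrix")
    if not np.isin(fps, (0, 1)).all():
        raise ValueError("fingerprints must be binary")
    return fps.astype(np.float64)


def tanimoto_matrix(fps: np.ndarray, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Tanimoto (Jaccard) distance 1 - A.B / (|A|^2 + |B|^2 - A.B)."""
    F = _check_fps(fps)
    counts = F.sum(axis=1)
    if (counts == 0).any():
        bad = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"fingerprint {bad} has no set bits: Tanimoto undefined")
    inter = F @ F.T
    union = counts[:, None] + counts[None, :] - inter
    d = 1.0 - inter / union
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    if ids is None:
        ids = [str(i) for i in range(F.shape[0])]
    return DistanceMatrix(ids=ids, values=d, metric_name="tanimoto")


def hamming_matrix(fps: np.ndarray, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Hamming distance: number of differing fingerprint positions."""
    F = _check_fps(fps)
    counts = F.sum(axis=1)
    inter = F @ F.T
    # |a XOR b| = |a| + |b| - 2 a.b
    d = counts[:, None] + counts[None, :] - 2.0 * inter
    d = np.rint(0.5 * (d + d.T))
    np.fill_diagonal(d, 0.0)
    if ids is None:
        ids = [str(i) for i in range(F.shape[0])]
    return DistanceMatrix(ids=ids, values=d, metric_name="hamming")


def levenshtein_distance(s: str, t: str) -> int:
    """Unit-cost edit distance between two strings."""
    import edlib

    if s == t:
        return 0
    if not s or not t:
        return max(len(s), len(t))
    return int(edlib.align(s, t, task="distance")["editDistance"])


def levenshtein_matrix(
    smiles: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    canonicalize: bool = False,
) -> DistanceMatrix:
    """Pairwise Levenshtein distances between SMILES strings.

    ``canonicalize=True`` converts each string to its canonical SMILES form
    first (only meaningful for chemically valid input); by default strings
    are compared exactly as stored.
    """
    strings = list(smiles)
    if canonicalize:
        from rdkit import Chem

        canon = []
        for s in strings:
            mol = Chem.MolFromSmiles(s)
            canon.append(Chem.MolToSmiles(mol) if mol is not None else s)
        strings = canon
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        if i and i % 200 == 0:
            logger.info("levenshtein_matrix: row %d/%d", i, n)
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein_distance(strings[i], strings[j])
    if ids is None:
        ids = [str(i) for i in range(n)]
    return DistanceMatrix(ids=ids, values=d, metric_name="levenshtein")
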