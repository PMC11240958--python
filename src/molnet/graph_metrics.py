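"""Weighted node metrics: degree, shortest paths, betweenness, Burt
constraint, and eigenvector centrality.

Conventions:

* weighted degree and eigenvector centrality operate on the similarity
  weights (``weight`` edge attribute);
* shortest paths and betweenness operate on the distance ``length``
  attribute ("shortest" is meaningful on dissimilarity only);
* the constraint score uses similarity-weighted tie proportions and is
  invariant to a global rescaling of the weights;
* eigenvector centrality is rescaled so that the maximum node value is
  exactly 1 on a connected graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedGraph

logger = logging.getLogger(__name__)


@dataclass
class CentralityResult:
    """Per-node centrality table for one network."""

    ids: Sequence[str]
    degree: np.ndarray
    betweenness: np.ndarray
    constraint: np.ndarray
    eigenvector: np.ndarray
    leading_eigenvalue: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": list(self.ids),
            "degree": self.degree,
            "betweenness": self.betweenness,
            "constraint": self.constraint,
            "eigenvector": self.eigenvector,
        })

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def weighted_degree(g: WeightedGraph) -> np.ndarray:
    """d_i = sum of similarity weights of edges incident to node i."""
    deg = g.graph.degree(weight="weight")
    return np.array([deg[i] for i in range(g.n)], dtype=float)


def shortest_path_matrix(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path lengths over the ``length`` attribute.

    Disconnected pairs get ``inf`` with a warning rather than failing
    silently.
    """
    n = g.n
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(g.graph, weight="length"):
        for dst, val in dists.items():
            out[src, dst] = val
    if np.isinf(out).any():
        warnings.warn("graph is disconnected: infinite shortest-path entries")
    return out


def betweenness_centrality(g: WeightedGraph) -> np.ndarray:
    """Unnormalised node betweenness over shortest paths on edge lengths.

    C_B(v) = sum_{s != v != t} sigma_st(v) / sigma_st, counting all
    shortest-path multiplicities, each unordered pair once.
    """
    if not g.is_connected():
        warnings.warn("graph is disconnected: betweenness computed per component")
    bc = nx.betweenness_centrality(g.graph, weight="length", normalized=False)
    return np.array([bc[i] for i in range(g.n)], dtype=float)


def constraint_score(g: WeightedGraph) -> np.ndarray:
    """Burt's constraint C_i = sum_j (p_ij + sum_k p_ik p_kj)^2.

    p_ij is the proportion of i's total tie weight allocated to neighbour
    j; k ranges over common neighbours of i and j (k != i, j).  Isolated
    nodes have undefined constraint and are reported as NaN with a
    warning.
    """
    A = g.similarity_matrix()
    n = g.n
    strength = A.sum(axis=1)
    out = np.full(n, np.nan)
    isolated = strength == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated node(s): constraint undefined")
    P = np.zeros_like(A)
    nz = ~isolated
    P[nz] = A[nz] / strength[nz, None]
    indirect = P @ P  # (P @ P)[i, j] = sum_k p_ik p_kj
    # with a zero diagonal, (P @ P)[i, j] sums exactly over common
    # neighbours k != i, j -- the open-neighbourhood Burt form
    for i in np.flatnonzero(nz):
        neigh = np.flatnonzero(A[i])
        terms = P[i, neigh] + indirect[i, neigh]
        out[i] = float((terms ** 2).sum())
    return out


def eigenvector_centrality(
    g: WeightedGraph,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Principal eigenvector of the similarity adjacency by power iteration.

    Returns (x, lambda) with x rescaled so max(x) = 1; on a connected
    graph with non-negative weights the Perron vector is positive, so the
    most central node scores exactly 1.  Convergence is on the max-norm of
    successive normalised iterates; a deterministic all-ones start vector
    is used.
    """
    if not g.is_connected():
        raise ValueError("eigenvector centrality requires a connected graph")
    A = g.similarity_matrix()
    if (A < 0).any():
        raise ValueError("negative weights")
    n = g.n
    x = np.ones(n)
    # positive diagonal shift: same Perron vector, but strictly dominant
    # eigenvalue even on bipartite graphs (spectrum +-lambda)
    shift = float(A.sum(axis=1).max())
    if shift == 0:
        raise ValueError("zero adjacency: eigenvector undefined")
    for _ in range(max_iter):
        y = A @ x + shift * x
        y /= float(np.linalg.norm(y))
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        lam = float(x @ (A @ x))
        residual = float(np.max(np.abs(A @ x - lam * x)))
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    lam = float(x @ (A @ x))  # Rayleigh quotient of the unit vector
    x = x / x.max()
    return x, lam


def compute_centralities(g: WeightedGraph) -> CentralityResult:
    """All node metrics for one network in a single table."""
    x, lam = eigenvector_centrality(g)
    return CentralityResult(
        ids=list(g.ids),
        degree=weighted_degree(g),
        betweenness=betweenness_centrality(g),
        constraint=constraint_score(g),
        eigenvector=x,
        leading_eigenvalue=lam,
    )


def edge_betweenness(g: WeightedGraph) -> dict[tuple[int, int], float]:
    """Secondary output: unnormalised edge betweenness on edge lengths."""
    return nx.edge_betweenness_centrality(g.graph, weight="length", normalized=False)
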