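"""Similarity graphs and sparsification: TMFG and MST.

A distance matrix is first mapped to similarities (edge "intensity" is
inversely related to distance), then filtered.  The Triangulated Maximally
Filtered Graph keeps exactly 3n - 6 edges: starting from the 4 mutually
most-similar vertices connected as a K4, each remaining vertex is inserted
into the triangular face whose three corners it is most similar to, which
preserves planarity by construction (every interior face is a 3-clique).

Edges carry two attributes: ``weight`` (similarity, used by modularity,
weighted degree and eigenvector centrality) and ``length`` (the original
distance, used by shortest-path-based measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .distances import DistanceMatrix


@dataclass
class WeightedGraph:
    """Filtered similarity network over an ordered set of node ids."""

    ids: Sequence[str]
    graph: nx.Graph
    build_method: str  # "tmfg" | "mst" | "complete"
    is_planar: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.build_method not in ("tmfg", "mst", "complete"):
            raise ValueError(f"unknown build method {self.build_method!r}")
        n = len(self.ids)
        if self.graph.number_of_nodes() != n:
            raise ValueError("node count mismatch")
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise ValueError("self-loop")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def similarity_matrix(self) -> np.ndarray:
        """Dense adjacency of similarity weights in id order."""
        return nx.to_numpy_array(self.graph, nodelist=range(self.n), weight="weight")

    def length_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=range(self.n), weight="length")

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def write_graphml(self, path: str) -> None:
        g = self.graph.copy()
        for i, node_id in enumerate(self.ids):
            g.nodes[i]["id"] = str(node_id)
        g.graph["build_method"] = self.build_method
        g.graph["is_planar"] = bool(self.is_planar)
        nx.write_graphml(g, path)

    @classmethod
    def read_graphml(cls, path: str) -> "WeightedGraph":
        g = nx.read_graphml(path, node_type=int)
        ids = [g.nodes[i]["id"] for i in sorted(g.nodes)]
        for i in g.nodes:
            del g.nodes[i]["id"]
        meta = g.graph
        return cls(ids=ids, graph=g, build_method=meta.get("build_method", "complete"),
                   is_planar=bool(meta.get("is_planar", False)))


def distance_to_similarity(d: DistanceMatrix, mode: str = "linear") -> np.ndarray:
    """Map distances to similarities in [0, 1], strictly decreasing in d.

    linear:  s = 1 - d / d_max  (d_max = max off-diagonal distance)
    inverse: s = 1 / (1 + d)
    """
    values = d.values
    off_diag = values[~np.eye(d.n, dtype=bool)]
    if off_diag.size == 0:
        raise ValueError("similarity undefined for fewer than 2 nodes")
    d_max = off_diag.max()
    if d_max == 0:
        raise ValueError("all molecules identical: similarity transform degenerate")
    if mode == "linear":
        s = 1.0 - values / d_max
    elif mode == "inverse":
        s = 1.0 / (1.0 + values)
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    np.fill_diagonal(s, 0.0)
    return s


def _graph_from_edges(n: int, edges, s: np.ndarray,
                      d: Optional[np.ndarray]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in edges:
        g.add_edge(int(i), int(j), weight=float(s[i, j]),
                   length=float(d[i, j]) if d is not None else float(s[i, j]))
    return g


def tmfg_filter(
    s: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    distances: Optional[DistanceMatrix] = None,
) -> WeightedGraph:
    """Triangulated Maximally Filtered Graph of a similarity matrix.

    Greedy construction: seed with the 4 vertices of largest total
    similarity (K4, 4 triangular faces), then repeatedly insert the
    (vertex, face) pair with the largest gain s(v,a)+s(v,b)+s(v,c),
    replacing the face with three new ones.  Ties break on the smallest
    (vertex index, face-creation index).  The result has 3n - 6 edges for
    n >= 4 (a triangle for n = 3), is planar and connected.
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if s.shape != (n, n) or not np.allclose(s, s.T):
        raise ValueError("similarity matrix must be square and symmetric")
    if n < 3:
        raise ValueError("TMFG needs at least 3 vertices")
    if ids is None:
        ids = distances.ids if distances is not None else [str(i) for i in range(n)]
    W = s.copy()
    np.fill_diagonal(W, 0.0)
    dvals = distances.values if distances is not None else None

    if n == 3:
        edges = [(0, 1), (0, 2), (1, 2)]
        g = _graph_from_edges(n, edges, W, dvals)
        return WeightedGraph(ids=ids, graph=g, build_method="tmfg", is_planar=True)

    # seed clique: 4 vertices with largest similarity row sums
    # (ties -> smallest index, via stable lexsort)
    row_sums = W.sum(axis=1)
    order = np.lexsort((np.arange(n), -row_sums))
    seed = sorted(int(v) for v in order[:4])
    edges: list[tuple[int, int]] = [
        (seed[a], seed[b]) for a in range(4) for b in range(a + 1, 4)
    ]

    # total face slots ever created: 4 seed faces + 3 per insertion
    max_faces = max(4, 3 * n - 8)
    faces = np.zeros((max_faces, 3), dtype=np.int64)
    active = np.zeros(max_faces, dtype=bool)
    faces[0] = (seed[0], seed[1], seed[2])
    faces[1] = (seed[0], seed[1], seed[3])
    faces[2] = (seed[0], seed[2], seed[3])
    faces[3] = (seed[1], seed[2], seed[3])
    active[:4] = True
    n_faces = 4

    remaining = np.ones(n, dtype=bool)
    remaining[seed] = False

    # gain[v, f] = total similarity of v to the corners of face f
    gain = np.full((n, max_faces), -np.inf)
    rem_idx = np.flatnonzero(remaining)
    for f in range(4):
        gain[rem_idx, f] = W[np.ix_(rem_idx, faces[f])].sum(axis=1)

    for _ in range(n - 4):
        masked = np.where(remaining[:, None] & active[None, :], gain, -np.inf)
        # C-order argmax: smallest vertex index, then smallest face index
        flat = int(np.argmax(masked))
        v, f = divmod(flat, max_faces)
        a, b, c = (int(x) for x in faces[f])
        edges.extend([(v, a), (v, b), (v, c)])
        remaining[v] = False
        active[f] = False
        rem_idx = np.flatnonzero(remaining)
        for corners in ((v, a, b), (v, a, c), (v, b, c)):
            faces[n_faces] = corners
            active[n_faces] = True
            if rem_idx.size:
                gain[rem_idx, n_faces] = W[np.ix_(rem_idx, list(corners))].sum(axis=1)
            n_faces += 1

    g = _graph_from_edges(n, edges, W, dvals)
    assert g.number_of_edges() == 3 * n - 6
    return WeightedGraph(ids=ids, graph=g, build_method="tmfg", is_planar=True)


def build_mst(d: DistanceMatrix, similarity: Optional[np.ndarray] = None,
              sim_mode: str = "linear") -> WeightedGraph:
    """Minimum spanning tree on distances (Kruskal), with similarity weights.

    The tree minimises total edge length; each edge also carries the
    similarity weight from the same transform used for the TMFG.
    """
    n = d.n
    if n < 2:
        raise ValueError("MST needs at least 2 nodes")
    if similarity is None:
        similarity = distance_to_similarity(d, mode=sim_mode)
    complete = nx.Graph()
    complete.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            complete.add_edge(i, j, length=float(d.values[i, j]))
    tree = nx.minimum_spanning_tree(complete, weight="length", algorithm="kruskal")
    g = _graph_from_edges(n, tree.edges(), similarity, d.values)
    planar, _ = nx.check_planarity(g)
    return WeightedGraph(ids=list(d.ids), graph=g, build_method="mst", is_planar=planar)
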