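"""Weighted graph topology of thresholded state matrices.

Only positive connections above the correlation threshold (strictly
r > r_min, default 0.2) enter the graph; weights are kept (no binarization).
Path lengths use the standard reciprocal transform L_ij = 1/W_ij, so
stronger connections are shorter. Efficiency definitions follow the weighted
reading: global efficiency is the mean inverse shortest path length over
ordered node pairs (1/inf = 0 for disconnected pairs), local efficiency of a
node is the global efficiency of the subgraph induced by its neighbors (0
for nodes with fewer than 2 neighbors), and betweenness centrality counts
fractional shortest-path contributions, normalized by (n-1)(n-2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .types import StateMatrix


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(W < 0):
            raise ValueError("no negative weights allowed")
        if np.any(np.diag(W) != 0):
            raise ValueError("no self-loops allowed")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def lengths(self) -> np.ndarray:
        """L_ij = 1/W_ij for existing edges, inf otherwise."""
        with np.errstate(divide="ignore"):
            L = np.where(self.weights > 0, 1.0 / self.weights, np.inf)
        np.fill_diagonal(L, 0.0)
        return L


@dataclass
class GraphMetrics:
    """Nodal and global topological properties of one weighted graph."""

    nodal_strength: np.ndarray
    nodal_ge: np.ndarray
    nodal_le: np.ndarray
    nodal_bc: np.ndarray
    total_strength: float
    global_ge: float
    global_le: float


def threshold_positive(mat: StateMatrix | np.ndarray, r_min: float = 0.2) -> WeightedGraph:
    """Keep entries strictly above ``r_min`` (negatives are always removed)."""
    M = mat.matrix if isinstance(mat, StateMatrix) else np.asarray(mat, float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    W = np.where(M > r_min, M, 0.0)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W)


def nodal_strength(g: WeightedGraph) -> np.ndarray:
    return g.weights.sum(axis=1)


def total_strength(g: WeightedGraph) -> float:
    """Sum of suprathreshold weights over unordered pairs (each edge once)."""
    return float(g.weights.sum() / 2.0)


def shortest_paths(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest path distances over lengths 1/W (inf if unreachable)."""
    n = g.n_nodes
    i, j = np.nonzero(np.triu(g.weights, k=1))
    lengths = 1.0 / g.weights[i, j]
    sparse = csr_matrix((lengths, (i, j)), shape=(n, n))
    return dijkstra(sparse, directed=False)


def _efficiency_from_distances(D: np.ndarray) -> tuple[np.ndarray, float]:
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return nodal, float(nodal.mean())


def nodal_global_efficiency(g: WeightedGraph) -> np.ndarray:
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return _efficiency_from_distances(shortest_paths(g))[0]


def global_efficiency(g: WeightedGraph) -> float:
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return _efficiency_from_distances(shortest_paths(g))[1]


def nodal_local_efficiency(g: WeightedGraph) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph (original weights)."""
    W = g.weights
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nb = np.flatnonzero(W[i] > 0)
        if nb.size < 2:
            continue
        sub = WeightedGraph(W[np.ix_(nb, nb)])
        out[i] = global_efficiency(sub)
    return out


def local_efficiency(g: WeightedGraph) -> float:
    if g.n_nodes == 0:
        return 0.0
    return float(nodal_local_efficiency(g).mean())


def betweenness(g: WeightedGraph) -> np.ndarray:
    """Normalized weighted betweenness centrality on lengths 1/W."""
    n = g.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(g.weights, k=1))
    for a, b in zip(i, j):
        G.add_edge(int(a), int(b), length=1.0 / g.weights[a, b])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[v] for v in range(n)])


def graph_metrics(g: WeightedGraph) -> GraphMetrics:
    """All nodal and global properties in one pass."""
    D = shortest_paths(g)
    nodal_ge, global_ge = _efficiency_from_distances(D)
    nodal_le = nodal_local_efficiency(g)
    return GraphMetrics(
        nodal_strength=nodal_strength(g),
        nodal_ge=nodal_ge,
        nodal_le=nodal_le,
        nodal_bc=betweenness(g),
        total_strength=total_strength(g),
        global_ge=global_ge,
        global_le=float(nodal_le.mean()),
    )


def state_metrics_table(
    mats: list[StateMatrix], r_min: float = 0.2
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Nodal and global metric tables over subject x state matrices.

    Thresholding is applied to each subject's state median matrix before
    metric computation. Returns (nodal table, global table).
    """
    import pandas as pd

    nodal_rows, global_rows = [], []
    for m in mats:
        g = threshold_positive(m, r_min=r_min)
        gm = graph_metrics(g)
        for node in range(g.n_nodes):
            nodal_rows.append(
                dict(
                    subject_id=m.subject_id, state_id=m.state_id, node_id=node,
                    strength=gm.nodal_strength[node], ge=gm.nodal_ge[node],
                    le=gm.nodal_le[node], bc=gm.nodal_bc[node],
                )
            )
        global_rows.append(
            dict(
                subject_id=m.subject_id, state_id=m.state_id,
                total_strength=gm.total_strength, global_ge=gm.global_ge,
                global_le=gm.global_le, n_frames=m.n_frames,
            )
        )
    return pd.DataFrame(nodal_rows), pd.DataFrame(global_rows)
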