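"""Inverse-cost graphs, minimum spanning trees, and global centrality.

Each per-epoch connectivity matrix becomes a complete graph whose edge cost
is the reciprocal of the AEC value (strong coupling = cheap link) and whose
edge weight is the AEC value itself.  The graph is reduced to its minimum
spanning tree — the cheapest acyclic backbone — and three node centralities
are computed on the tree: betweenness (shortest-path mediation, raw pair
counts), closeness (inverse mean cost-weighted distance), and eigenvector
centrality on the AEC-weighted adjacency.  Per band and time point, each
measure is averaged over epochs, normalized so the most central region
scores exactly 1, and the three normalized measures are averaged into a
single "global centrality" per region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Floor applied to AEC values before inversion into costs.
COST_EPS = 1e-12


@dataclass
class CostGraph:
    """Complete graph over ROIs with cost = 1/AEC and weight = AEC."""

    weights: np.ndarray  # symmetric AEC matrix (diagonal ignored)
    costs: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class MSTGraph:
    """A minimum spanning tree: ``n - 1`` edges with their costs and weights."""

    n_nodes: int
    edges: list[tuple[int, int, float, float]]  # (i, j, cost, weight), i < j

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree has exactly n - 1 edges")

    @property
    def total_cost(self) -> float:
        return float(sum(e[2] for e in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j, cost, weight in self.edges:
            g.add_edge(i, j, cost=cost, weight=weight)
        return g

    def weight_adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, _, weight in self.edges:
            a[i, j] = a[j, i] = weight
        return a


@dataclass
class CentralityTable:
    """Epoch-averaged, max-normalized centralities per ROI (one band/time point)."""

    roi_names: list[str]
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray
    global_centrality: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"betweenness": self.betweenness, "closeness": self.closeness,
             "eigenvector": self.eigenvector, "global": self.global_centrality},
            index=self.roi_names,
        )


def build_cost_graph(values: np.ndarray, eps: float = COST_EPS) -> CostGraph:
    """Invert AEC values into link costs, flooring at ``eps`` to stay finite."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("connectivity matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("connectivity values must be nonnegative")
    costs = 1.0 / np.maximum(values, eps)
    return CostGraph(weights=values, costs=costs)


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def minimum_spanning_tree(g: CostGraph) -> MSTGraph:
    """Kruskal's algorithm with deterministic tie-breaking.

    Edges are examined in order of (cost, smaller node, larger node), so equal
    costs resolve to the lexicographically first edge — ties are measure-zero
    for continuous AEC but show up in toy inputs.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, g.costs[iu, ju]))
    dsu = _DisjointSet(n)
    edges: list[tuple[int, int, float, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if dsu.union(i, j):
            edges.append((i, j, float(g.costs[i, j]), float(g.weights[i, j])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("graph is disconnected; no spanning tree exists")
    return MSTGraph(n_nodes=n, edges=edges)


def betweenness(t: MSTGraph) -> np.ndarray:
    """Raw betweenness: node pairs whose unique tree path crosses the node.

    Paths on a tree are unique, so no weighting is involved; leaves score 0.
    """
    bc = nx.betweenness_centrality(t.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(t.n_nodes)])


def closeness(t: MSTGraph) -> np.ndarray:
    """Closeness ``(n-1) / sum_j d(i, j)`` with cost-weighted tree distances."""
    cc = nx.closeness_centrality(t.to_networkx(), distance="cost")
    return np.array([cc[i] for i in range(t.n_nodes)])


def eigenvector(t: MSTGraph, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Leading eigenvector of the AEC-weighted tree adjacency, by power iteration.

    The tree is connected and the weights nonnegative, so the Perron vector is
    nonnegative and unique up to scale; it is returned with unit 2-norm.
    """
    a = t.weight_adjacency()
    if not a.any():
        raise ValueError("all edge weights zero; eigenvector centrality undefined")
    # trees are bipartite (spectrum symmetric about 0); a positive diagonal
    # shift breaks the +/- lambda oscillation without changing the eigenvector
    shift = float(a.sum(axis=1).max())
    a = a + shift * np.eye(t.n_nodes)
    v = np.full(t.n_nodes, 1.0 / np.sqrt(t.n_nodes))
    for _ in range(max_iter):
        nv = a @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero")
        nv /= norm
        if np.linalg.norm(nv - v) < tol:
            return np.abs(nv)
        v = nv
    # near-degenerate leading eigenvalues (common on large weighted trees)
    # stall the iteration; finish with an exact symmetric eigendecomposition
    logger.debug("power iteration stalled after %d iterations; using eigh", max_iter)
    w, vecs = np.linalg.eigh(a)
    return np.abs(vecs[:, -1])


def tree_centralities(t: MSTGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(betweenness, closeness, eigenvector) for one tree."""
    return betweenness(t), closeness(t), eigenvector(t)


def global_centrality(per_epoch: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                      roi_names: list[str]) -> CentralityTable:
    """Average each measure over epochs, max-normalize, and combine.

    Normalization divides by the maximum over ROIs so the most central region
    scores exactly 1 per measure.  A measure that is identically zero across
    ROIs (betweenness on a 2-node tree) is left at zero with a warning and the
    global centrality is the mean of the remaining measures.
    """
    if not per_epoch:
        raise ValueError("need at least one epoch of centralities")
    stacked = [np.mean([trip[k] for trip in per_epoch], axis=0) for k in range(3)]
    normalized = []
    active = []
    for name, mean_vals in zip(("betweenness", "closeness", "eigenvector"), stacked):
        peak = mean_vals.max()
        if peak == 0:
            warnings.warn(f"{name} is identically zero; dropped from the composite")
            normalized.append(np.zeros_like(mean_vals))
        else:
            normalized.append(mean_vals / peak)
            active.append(normalized[-1])
    global_c = np.mean(active, axis=0) if active else np.zeros_like(stacked[0])
    return CentralityTable(roi_names=list(roi_names), betweenness=normalized[0],
                           closeness=normalized[1], eigenvector=normalized[2],
                           global_centrality=global_c)


def centrality_from_matrices(matrices: list[np.ndarray],
                             roi_names: list[str]) -> CentralityTable:
    """Convenience: per-epoch AEC matrices -> MSTs -> global centrality."""
    per_epoch = [tree_centralities(minimum_spanning_tree(build_cost_graph(m)))
                 for m in matrices]
    return global_centrality(per_epoch, roi_names)


def centrality_delta(pre: CentralityTable, post: CentralityTable) -> pd.Series:
    """Post minus pre global centrality per ROI, on the shared ROI set."""
    pre_s = pd.Series(pre.global_centrality, index=pre.roi_names)
    post_s = pd.Series(post.global_centrality, index=post.roi_names)
    common = pre_s.index.intersection(post_s.index)
    if len(common) < len(pre_s) or len(common) < len(post_s):
        logger.warning("ROI sets differ; delta restricted to %d shared ROIs",
                       len(common))
    return post_s[common] - pre_s[common]
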