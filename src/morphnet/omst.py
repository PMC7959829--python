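"""Threshold-free topological filtering via orthogonal minimal spanning trees.

Similarity matrices are first absolutized (a strong negative correlation is
as informative a connection as a strong positive one).  OMST then unions
successive edge-disjoint ("orthogonal") maximum spanning trees: round m
adds the heaviest spanning tree among edges not yet selected.  After each
round the global cost efficiency GCE(m) = GE_w(union) - Cost(m) is
evaluated, where Cost(m) is the selected weight fraction of total weight
and GE_w is weighted global efficiency with edge distance 1/w.  The union
at the GCE-maximizing round is returned, binarized.  Because round 1 is a
spanning tree, the output always spans and connects all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from morphnet.errors import DisconnectedGraphError, ValidationError
from morphnet.similarity import SimilarityMatrix

Edge = tuple[int, int]  # (i, j) with i < j


@dataclass
class WeightedGraph:
    """Symmetric non-negative weights on parcel nodes, no self-loops."""

    labels: tuple[str, ...]
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge_list(self) -> list[tuple[Edge, float]]:
        """Positive-weight edges (i<j) with weights."""
        n = self.n_nodes
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w > 0:
                    out.append(((i, j), float(w)))
        return out


@dataclass
class BinaryGraph:
    """Undirected unweighted adjacency; the substrate for efficiency metrics."""

    labels: tuple[str, ...]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class OmstDiagnostics:
    """Per-round bookkeeping of the OMST selection criterion."""

    table: pd.DataFrame  # columns: round, n_edges, cost, ge_weighted, gce
    chosen_round: int


def absolutize(s: SimilarityMatrix) -> WeightedGraph:
    """Absolute-value connection weights; the diagonal is dropped."""
    w = np.abs(np.asarray(s.matrix, dtype=float)).copy()
    np.fill_diagonal(w, 0.0)
    if not np.allclose(w, w.T):
        raise ValidationError("similarity matrix must be symmetric")
    return WeightedGraph(labels=s.labels, weights=w)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(
    g: WeightedGraph, excluded_edges: frozenset[Edge] | set[Edge] = frozenset()
) -> frozenset[Edge] | None:
    """Kruskal maximum spanning tree over non-excluded positive-weight edges.

    Ties are broken deterministically: edges are taken in order of
    (descending weight, ascending (i, j)), so equal weights yield the
    lexicographically smallest edge set.  Returns ``None`` when the
    restricted graph is disconnected (no further orthogonal tree exists).
    """
    n = g.n_nodes
    candidates = [
        (e, w) for e, w in g.edge_list() if e not in excluded_edges
    ]
    candidates.sort(key=lambda ew: (-ew[1], ew[0]))
    uf = _UnionFind(n)
    tree: list[Edge] = []
    for (i, j), _w in candidates:
        if uf.union(i, j):
            tree.append((i, j))
            if len(tree) == n - 1:
                return frozenset(tree)
    return None


def binarize(edges, labels: tuple[str, ...]) -> BinaryGraph:
    """Adjacency with 1 exactly on the selected edges (symmetric)."""
    n = len(labels)
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValidationError(f"edge ({i}, {j}) references unknown node")
        adj[i, j] = adj[j, i] = 1
    np.fill_diagonal(adj, 0)
    return BinaryGraph(labels=labels, adjacency=adj)


def _edge_distance(w: float, transform: str) -> float:
    if transform == "inverse":
        return 1.0 / w
    if transform == "one-minus":
        # weights are in (0, 1]; guard exact 1 with a tiny floor
        return max(1.0 - w, np.finfo(float).tiny)
    raise ValueError(f"unknown distance transform {transform!r}")


def weighted_global_efficiency(
    g: WeightedGraph, edges, transform: str = "inverse"
) -> float:
    """GE_w of the subgraph on ``edges``: mean 1/shortest-distance, d = 1/w."""
    n = g.n_nodes
    dist = np.full((n, n), np.inf)
    for i, j in edges:
        d = _edge_distance(g.weights[i, j], transform)
        dist[i, j] = dist[j, i] = d
    sp = dijkstra(dist, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def omst_select(
    g: WeightedGraph,
    max_rounds: int | None = None,
    distance: str = "inverse",
) -> tuple[BinaryGraph, OmstDiagnostics]:
    """Union orthogonal maximum spanning trees; keep the GCE-maximizing round.

    Rounds proceed while an edge-disjoint spanning tree still exists, up to
    ``max_rounds`` (default N - 1).  The argmax of GCE is taken over all
    completed rounds (global, not first-decline); the first round achieving
    the maximum wins ties.  The returned graph is the binarized union of
    trees 1..m*, hence connected and spanning.
    """
    n = g.n_nodes
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if max_rounds is None:
        max_rounds = n - 1
    total_weight = sum(w for _e, w in g.edge_list())
    if total_weight <= 0:
        raise DisconnectedGraphError("graph has no positive-weight edges")

    excluded: set[Edge] = set()
    rounds: list[frozenset[Edge]] = []
    records = []
    union: set[Edge] = set()
    for m in range(1, max_rounds + 1):
        tree = maximum_spanning_tree(g, frozenset(excluded))
        if tree is None:
            if m == 1:
                raise DisconnectedGraphError(
                    "input graph is disconnected on its positive-weight edges"
                )
            break
        rounds.append(tree)
        excluded |= tree
        union |= tree
        cost = sum(g.weights[i, j] for i, j in union) / total_weight
        ge_w = weighted_global_efficiency(g, union, transform=distance)
        records.append(
            {
                "round": m,
                "n_edges": len(union),
                "cost": cost,
                "ge_weighted": ge_w,
                "gce": ge_w - cost,
            }
        )

    table = pd.DataFrame(records)
    m_star = int(table.loc[table["gce"].idxmax(), "round"])
    selected: set[Edge] = set()
    for tree in rounds[:m_star]:
        selected |= tree
    bg = binarize(sorted(selected), g.labels)
    return bg, OmstDiagnostics(table=table, chosen_round=m_star)
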