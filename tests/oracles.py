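"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths of the package: shortest paths by
Floyd-Warshall (min-plus) instead of BFS, efficiencies by literal
evaluation of their defining sums, spanning trees by exhaustive edge-set
enumeration instead of Kruskal, and BH-FDR by the step-up definition.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by min-plus dynamic programming."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def batched_floyd_warshall(adjs: np.ndarray) -> np.ndarray:
    """Floyd-Warshall over a stack of graphs, shape (G, n, n)."""
    n = adjs.shape[1]
    d = np.where(adjs > 0, 1.0, np.inf)
    eye = np.eye(n, dtype=bool)
    d[:, eye] = 0.0
    for k in range(n):
        d = np.minimum(d, d[:, :, k, None] + d[:, None, k, :])
    return d


def global_eff(adj: np.ndarray) -> float:
    """Literal evaluation of the mean-inverse-distance definition."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_eff(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def local_eff(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each explicitly constructed neighbor subgraph."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = global_eff(sub)
    return out


def connected_graph_generator(n: int):
    """Yield adjacency matrices of every connected labeled graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=np.int8)
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                adj[i, j] = adj[j, i] = 1
        if np.isfinite(floyd_warshall(adj)).all():
            yield adj


def all_connected_adjacencies(n: int) -> np.ndarray:
    """Stack of all connected labeled graphs on n nodes (vectorized filter)."""
    pairs = list(itertools.combinations(range(n), 2))
    m = len(pairs)
    bits = np.arange(2**m)[:, None] >> np.arange(m) & 1
    adjs = np.zeros((2**m, n, n), dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        adjs[:, i, j] = adjs[:, j, i] = bits[:, k]
    d = batched_floyd_warshall(adjs)
    connected = np.isfinite(d).all(axis=(1, 2))
    return adjs[connected]


def is_spanning_tree(edges, n: int) -> bool:
    if len(edges) != n - 1:
        return False
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            return False
        parent[rj] = ri
    return True


def max_spanning_tree_enumerated(weights: np.ndarray, available: set) -> frozenset | None:
    """Heaviest spanning tree by exhaustive enumeration of edge subsets."""
    n = weights.shape[0]
    edges = sorted(available)
    best, best_w = None, -np.inf
    for combo in itertools.combinations(edges, n - 1):
        if is_spanning_tree(combo, n):
            w = sum(weights[i, j] for i, j in combo)
            if w > best_w:
                best, best_w = frozenset(combo), w
    return best


def omst_oracle(weights: np.ndarray, transform: str = "inverse"):
    """Exhaustive orthogonal-MST rounds with networkx weighted efficiency.

    Returns (selected edge union, chosen round, per-round GCE list).
    """
    import networkx as nx

    n = weights.shape[0]
    all_edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i, j] > 0
    }
    total_w = sum(weights[i, j] for i, j in all_edges)
    available = set(all_edges)
    union: set = set()
    rounds = []
    gces = []
    while len(rounds) < n - 1:
        tree = max_spanning_tree_enumerated(weights, available)
        if tree is None:
            break
        rounds.append(tree)
        available -= tree
        union |= tree
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in union:
            d = 1.0 / weights[i, j] if transform == "inverse" else 1.0 - weights[i, j]
            g.add_edge(i, j, dist=d)
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="dist"))
        ge = sum(
            1.0 / sp[i][j]
            for i in range(n)
            for j in range(n)
            if i != j and j in sp[i]
        ) / (n * (n - 1))
        cost = sum(weights[i, j] for i, j in union) / total_w
        gces.append(ge - cost)
    m_star = int(np.argmax(gces)) + 1
    selected: set = set()
    for tree in rounds[:m_star]:
        selected |= tree
    return frozenset(selected), m_star, gces


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """q-values from the literal step-up definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
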