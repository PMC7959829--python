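"""Binary-graph efficiency metrics: global, nodal, local.

Global efficiency is the mean inverse shortest-path length over all
ordered node pairs (1/inf := 0 for unreachable pairs); nodal efficiency is
the same mean restricted to one source node, so the node-average of nodal
efficiency equals global efficiency exactly.  Local efficiency of node i
is the global efficiency of the subgraph induced on i's neighbors (i
excluded); nodes of degree < 2 get 0, since the measure is undefined on
fewer than two nodes.

All metrics are computed on binary (unweighted) graphs; shortest paths are
hop counts found by level-synchronous breadth-first search over all
sources at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from morphnet.omst import BinaryGraph


@dataclass
class EfficiencyProfile:
    """Global scalar plus per-node nodal and local efficiency vectors."""

    subject_id: str
    measure: str
    labels: tuple[str, ...]
    e_global: float
    e_nodal: np.ndarray
    e_local: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject_id, measure, metric, parcel, value)."""
        rows = [
            {
                "subject_id": self.subject_id,
                "measure": self.measure,
                "metric": "global",
                "parcel": "ALL",
                "value": self.e_global,
            }
        ]
        for metric, vec in (("nodal", self.e_nodal), ("local", self.e_local)):
            for label, val in zip(self.labels, vec):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "measure": self.measure,
                        "metric": metric,
                        "parcel": label,
                        "value": float(val),
                    }
                )
        return pd.DataFrame(rows)


def _as_adjacency(g) -> np.ndarray:
    adj = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return adj.astype(bool)


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs hop counts; inf for unreachable pairs, 0 on the diagonal."""
    a = _as_adjacency(g)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    for hops in range(1, n):
        frontier = (frontier @ a) & ~reached
        if not frontier.any():
            break
        dist[frontier] = hops
        reached |= frontier
    return dist


def _inverse_distance_sum(dist: np.ndarray) -> np.ndarray:
    """Row sums of 1/L over off-diagonal entries, with 1/inf := 0."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1)


def global_efficiency(g) -> float:
    """Mean inverse shortest path length over ordered pairs; in [0, 1]."""
    a = _as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(_inverse_distance_sum(shortest_path_lengths(a)).sum() / (n * (n - 1)))


def nodal_efficiency(g) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    a = _as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    return _inverse_distance_sum(shortest_path_lengths(a)) / (n - 1)


def local_efficiency(g) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph.

    The subgraph excludes the node itself; it may be disconnected even
    when the whole graph is connected, which is why unreachable pairs
    contribute 0.  Degree-0 and degree-1 nodes get 0.
    """
    a = _as_adjacency(g)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def efficiency_profile(
    bg: BinaryGraph, subject_id: str = "", measure: str = ""
) -> EfficiencyProfile:
    """All three efficiency metrics of one binary graph."""
    nodal = nodal_efficiency(bg)
    return EfficiencyProfile(
        subject_id=subject_id,
        measure=measure,
        labels=bg.labels,
        e_global=float(nodal.mean()),
        e_nodal=nodal,
        e_local=local_efficiency(bg),
    )
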