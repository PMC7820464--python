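"""Pairwise SPIKE-synchronization and Louvain community networks.

SPIKE-synchronization is the parameter-free coincidence measure: each spike
is coincident if the partner train has a spike within an adaptive window
``τ = 0.5 * min`` of the four adjacent inter-spike intervals (the spike's
own previous/next ISI and those around the nearest partner spike).  The
score is the fraction of coincident spikes over both trains, 0 (asynchrony)
to 1 (every spike matched).

Electrode pairs scoring above the link threshold (default 0.5, strict)
form a weighted graph; communities are extracted with a seeded two-phase
Louvain modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .core import SpikeTrainSet

__all__ = [
    "NetworkParams",
    "SyncMatrix",
    "Partition",
    "spike_synchronization",
    "sync_matrix",
    "build_graph",
    "modularity",
    "louvain_partition",
    "network_summaries",
]


@dataclass
class NetworkParams:
    link_threshold: float = 0.5
    louvain_resolution: float = 1.0
    seed: int = 0
    min_community_size: int = 2
    louvain_restarts: int = 20  # seeded visit-order restarts, best kept

    def __post_init__(self) -> None:
        if not 0 < self.link_threshold < 1:
            raise ValueError("link threshold must be in (0, 1)")
        if self.louvain_restarts < 1:
            raise ValueError("need at least one Louvain restart")


@dataclass
class SyncMatrix:
    """Symmetric electrode-by-electrode synchronization scores in [0, 1]."""

    scores: np.ndarray
    electrode_ids: List[int]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape[0] != s.shape[1] or s.shape[0] != len(self.electrode_ids):
            raise ValueError("score matrix shape must match electrode ids")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")
        if s.size and (np.nanmin(s) < 0 or np.nanmax(s) > 1):
            raise ValueError("scores must lie in [0, 1]")
        self.scores = s


@dataclass
class Partition:
    """Louvain community labels plus the graph statistics derived from them."""

    labels: Dict[int, int]               # node -> contiguous community label
    modularity: float
    normalized_degree: Dict[int, float] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def community_sizes(self) -> Dict[int, int]:
        sizes: Dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


# -- SPIKE-synchronization ---------------------------------------------------

def _coincident(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean per-spike coincidence flags for spikes of ``a`` against ``b``."""
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        return np.zeros(na, dtype=bool)
    idx = np.searchsorted(b, a)
    left = np.clip(idx - 1, 0, nb - 1)
    right = np.clip(idx, 0, nb - 1)
    d_left = np.abs(a - b[left])
    d_right = np.abs(a - b[right])
    nearest = np.where(d_right < d_left, right, left)
    d_min = np.minimum(d_left, d_right)

    inf = np.inf
    isi_a = np.diff(a)
    isi_b = np.diff(b)
    own_prev = np.concatenate([[inf], isi_a]) if na > 1 else np.full(na, inf)
    own_next = np.concatenate([isi_a, [inf]]) if na > 1 else np.full(na, inf)
    if nb > 1:
        partner_prev = np.where(nearest > 0, np.concatenate([[inf], isi_b])[nearest], inf)
        partner_next = np.where(nearest < nb - 1, np.concatenate([isi_b, [inf]])[nearest], inf)
    else:
        partner_prev = np.full(na, inf)
        partner_next = np.full(na, inf)
    tau = 0.5 * np.minimum.reduce([own_prev, own_next, partner_prev, partner_next])
    return d_min < tau


def spike_synchronization(train_a: np.ndarray, train_b: np.ndarray) -> float:
    """SPIKE-synchronization score of two sorted trains.

    Conventions: both trains empty -> 1.0 (trivially matched); exactly one
    empty -> 0.0.  Edge spikes lacking an adjacent ISI draw their window
    from the remaining defined ISIs; for two single-spike trains the window
    is unbounded and the pair counts as coincident.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 and b.size == 0:
        return 1.0
    if a.size == 0 or b.size == 0:
        return 0.0
    c = int(_coincident(a, b).sum()) + int(_coincident(b, a).sum())
    return c / (a.size + b.size)


def sync_matrix(train_set: SpikeTrainSet) -> SyncMatrix:
    """Score all unordered electrode pairs; diagonal fixed at 1."""
    ids = train_set.channel_ids
    n = len(ids)
    scores = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = spike_synchronization(train_set.trains[ids[i]],
                                      train_set.trains[ids[j]])
            scores[i, j] = scores[j, i] = s
    return SyncMatrix(scores=scores, electrode_ids=ids)


# -- graph construction and Louvain -----------------------------------------

def build_graph(matrix: SyncMatrix, params: Optional[NetworkParams] = None,
                positions: Optional[Dict[int, Sequence[float]]] = None,
                include: Optional[Sequence[int]] = None) -> nx.Graph:
    """Weighted graph with an edge wherever the score strictly exceeds the
    link threshold; no self-loops.  Optional 3D electrode coordinates are
    attached as node attributes for map export.  ``include`` restricts the
    graph to a subset of electrodes (typically the active ones, since the
    empty-train score convention would otherwise link silent channels)."""
    params = params or NetworkParams()
    g = nx.Graph()
    ids = matrix.electrode_ids
    keep = set(ids if include is None else include)
    ids = [e for e in ids if e in keep]
    index = {e: i for i, e in enumerate(matrix.electrode_ids)}
    for eid in ids:
        attrs = {}
        if positions is not None and eid in positions:
            x, y, z = positions[eid]
            attrs = {"x": float(x), "y": float(y), "z": float(z)}
        g.add_node(eid, **attrs)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.scores[index[ids[i]], index[ids[j]]]
            if w > params.link_threshold:
                g.add_edge(ids[i], ids[j], weight=float(w))
    return g


def modularity(graph: nx.Graph, labels: Dict[int, int],
               resolution: float = 1.0) -> float:
    """Weighted Newman modularity of a labelling of ``graph``."""
    m2 = 2.0 * graph.size(weight="weight")
    if m2 == 0:
        return 0.0
    degrees = dict(graph.degree(weight="weight"))
    q = 0.0
    for u, v, data in graph.edges(data=True):
        if labels[u] == labels[v]:
            q += 2.0 * data.get("weight", 1.0)
    for nodes_in_c in _groups(labels).values():
        dc = sum(degrees[u] for u in nodes_in_c)
        q -= resolution * dc * dc / m2
    return q / m2


def _groups(labels: Dict[int, int]) -> Dict[int, List[int]]:
    out: Dict[int, List[int]] = {}
    for node, c in labels.items():
        out.setdefault(c, []).append(node)
    return out


def _local_move(adj: Dict[int, Dict[int, float]], degrees: Dict[int, float],
                m2: float, labels: Dict[int, int], resolution: float,
                rng: np.random.Generator) -> bool:
    """One phase of greedy node moves; returns whether anything moved."""
    nodes = list(adj)
    improved = False
    moved = True
    while moved:
        moved = False
        order = [nodes[i] for i in rng.permutation(len(nodes))]
        for u in order:
            cu = labels[u]
            # weight from u to each neighboring community (u removed from its own)
            w_to: Dict[int, float] = {}
            for v, w in adj[u].items():
                if v == u:
                    continue
                w_to[labels[v]] = w_to.get(labels[v], 0.0) + w
            sum_tot: Dict[int, float] = {}
            for c in set(w_to) | {cu}:
                sum_tot[c] = sum(degrees[v] for v, lc in labels.items() if lc == c)
            sum_tot[cu] -= degrees[u]
            best_c, best_gain = cu, w_to.get(cu, 0.0) - resolution * sum_tot[cu] * degrees[u] / m2
            for c in sorted(w_to):
                gain = w_to[c] - resolution * sum_tot[c] * degrees[u] / m2
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            if best_gain < -1e-12:
                # isolating the node beats every neighbouring community
                best_c = max(labels.values()) + 1
            if best_c != cu:
                labels[u] = best_c
                moved = improved = True
    return improved


def louvain_partition(graph: nx.Graph,
                      params: Optional[NetworkParams] = None) -> Partition:
    """Two-phase Louvain modularity maximization with seeded restarts.

    Local greedy moves (seeded visit order, ties broken toward the lowest
    community label) alternate with community aggregation until a full pass
    no longer improves modularity, which is non-decreasing across passes.
    The procedure restarts ``louvain_restarts`` times with different visit
    orders and keeps the highest-modularity partition, mitigating the greedy
    heuristic's local optima; everything is deterministic under the seed.
    """
    params = params or NetworkParams()
    rng = np.random.default_rng(params.seed)
    best: Optional[Partition] = None
    for _ in range(params.louvain_restarts):
        cand = _louvain_once(graph, params, rng)
        if best is None or cand.modularity > best.modularity + 1e-15:
            best = cand
    return best


def _louvain_once(graph: nx.Graph, params: NetworkParams,
                  rng: np.random.Generator) -> Partition:
    nodes = list(graph.nodes)
    n_all = len(nodes)

    # current mapping original node -> community of the aggregated graph
    assignment = {u: i for i, u in enumerate(sorted(nodes, key=_node_key))}
    adj: Dict[int, Dict[int, float]] = {i: {} for i in range(len(nodes))}
    for u, v, data in graph.edges(data=True):
        iu, iv = assignment[u], assignment[v]
        w = float(data.get("weight", 1.0))
        adj[iu][iv] = adj[iu].get(iv, 0.0) + w
        adj[iv][iu] = adj[iv].get(iu, 0.0) + w

    m2 = 2.0 * graph.size(weight="weight")
    if m2 > 0:
        while True:
            labels = {i: i for i in adj}
            degrees = {
                i: sum(w for w in adj[i].values()) + adj[i].get(i, 0.0) for i in adj
            }
            improved = _local_move(adj, degrees, m2, labels, params.louvain_resolution, rng)
            if not improved:
                break
            # aggregate: communities become supernodes, intra-weight self-loops
            relabel = {c: k for k, c in enumerate(sorted(set(labels.values())))}
            assignment = {u: relabel[labels[assignment[u]]] for u in assignment}
            new_adj: Dict[int, Dict[int, float]] = {k: {} for k in relabel.values()}
            for i, nbrs in adj.items():
                ci = relabel[labels[i]]
                for j, w in nbrs.items():
                    if j < i:
                        continue  # visit each undirected pair (and self-loop) once
                    cj = relabel[labels[j]]
                    if i == j or ci == cj:
                        new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                    else:
                        new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                        new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
            adj = new_adj

    # contiguous final labels ordered by smallest member node
    groups = _groups({u: assignment[u] for u in nodes})
    ordered = sorted(groups.values(), key=lambda g: _node_key(min(g, key=_node_key)))
    final = {}
    for k, members in enumerate(ordered):
        for u in members:
            final[u] = k
    q = modularity(graph, final, params.louvain_resolution)
    norm_deg = {
        u: (graph.degree(u, weight=None) / (n_all - 1) if n_all > 1 else 0.0)
        for u in nodes
    }
    return Partition(labels=final, modularity=q, normalized_degree=norm_deg)


def _node_key(u):
    return (0, u) if isinstance(u, (int, np.integer)) else (1, str(u))


def network_summaries(partition: Partition, graph: nx.Graph,
                      params: Optional[NetworkParams] = None) -> Dict[str, object]:
    """Counts of functional networks and their mean size.

    A "network" is a community with at least ``min_community_size``
    electrodes (singletons are isolated electrodes, not networks).
    Normalized degree is the per-node degree over N-1.
    """
    params = params or NetworkParams()
    sizes = [s for s in partition.community_sizes().values()
             if s >= params.min_community_size]
    return {
        "n_networks": len(sizes),
        "mean_network_size": float(np.mean(sizes)) if sizes else 0.0,
        "network_sizes": sorted(sizes, reverse=True),
        "normalized_degree": dict(partition.normalized_degree),
    }
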