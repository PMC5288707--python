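"""Structural centrality baselines: static and temporal degree, closeness
and betweenness.

Static variants act on the binary aggregated network.  Temporal variants act
on the time-ordered expansion of the snapshot sequence, in which a
time-respecting path moves across a contact edge of snapshot ``s`` between
steps ``s-1`` and ``s`` or waits in place, and the temporal distance from a
source (observed from ``start``) to a target is its earliest arrival step,
counted as ``arrival - start + 1``.

These are ranking baselines: none of them is normalized, since rank
correlation against simulated influence is invariant to positive rescaling.
Exact definitional choices (harmonic fallback for disconnected aggregates,
ordered pairs in temporal betweenness) are recorded in each docstring and in
the score metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tdc_core import CentralityScores
from .tempnet import AggregatedNetwork, Node, TemporalNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalDistanceTable",
    "static_degree",
    "static_closeness",
    "static_betweenness",
    "temporal_distances",
    "temporal_distance_table",
    "temporal_degree",
    "temporal_closeness",
    "temporal_betweenness",
]


# ---------------------------------------------------------------------------
# Static benchmarks (aggregated network)
# ---------------------------------------------------------------------------

def static_degree(agg: AggregatedNetwork) -> CentralityScores:
    """Number of distinct neighbours in the aggregated binary network."""
    deg = np.asarray(agg.binary_adjacency.sum(axis=1)).ravel()
    return CentralityScores(
        scores=dict(zip(agg.nodes, deg.tolist())),
        method="sd",
        params={"definition": "aggregated binary degree"},
    )


def static_closeness(agg: AggregatedNetwork) -> CentralityScores:
    """Reciprocal of the sum of shortest-path distances, ``1 / sum_j d_ij``.

    That form is undefined on disconnected aggregates, so when the graph is
    disconnected the harmonic variant ``sum_j 1/d_ij`` (unreachable pairs
    contributing 0) is used instead, with a log notice.
    """
    g = agg.to_graph()
    n = agg.n_nodes
    connected = n > 0 and nx.is_connected(g) if g.number_of_nodes() else False
    if not connected and n > 1:
        logger.info(
            "aggregated network disconnected: static closeness falls back to "
            "the harmonic form sum(1/d)"
        )
    scores = {}
    for u in agg.nodes:
        dists = nx.single_source_shortest_path_length(g, u)
        if connected and n > 1:
            total = sum(d for v, d in dists.items() if v != u)
            scores[u] = 1.0 / total if total > 0 else 0.0
        else:
            scores[u] = sum(1.0 / d for v, d in dists.items() if v != u)
    return CentralityScores(
        scores=scores,
        method="sc",
        params={"definition": "1/sum(d)" if connected else "harmonic sum(1/d)"},
    )


def static_betweenness(agg: AggregatedNetwork) -> CentralityScores:
    """Shortest-path betweenness ``sum_{j<k, j,k != i} sigma_jk(i)/sigma_jk``
    on the aggregated binary network; unordered pairs counted once,
    endpoints excluded."""
    g = agg.to_graph()
    bc = nx.betweenness_centrality(g, normalized=False)
    return CentralityScores(
        scores={u: float(bc.get(u, 0.0)) for u in agg.nodes},
        method="sb",
        params={"definition": "unnormalized shortest-path betweenness"},
    )


# ---------------------------------------------------------------------------
# Temporal path machinery
# ---------------------------------------------------------------------------

@dataclass
class TemporalDistanceTable:
    """Earliest-arrival temporal distances for a set of sources.

    ``distances[(i, j)]`` is the number of steps after ``start`` by which
    ``j`` is first reached from ``i`` (``0`` for ``i`` itself), or ``None``
    when no time-respecting path exists inside the window."""

    distances: dict[tuple[Node, Node], int | None]
    window: tuple[int, int]

    def row(self, source: Node) -> dict[Node, int | None]:
        return {j: d for (i, j), d in self.distances.items() if i == source}


def _check_window(net: TemporalNetwork, window: tuple[int, int]) -> tuple[int, int]:
    start, end = window
    if not (1 <= start <= end <= net.n_snapshots):
        raise ValueError(
            f"invalid window {window}; need 1 <= start <= end <= L={net.n_snapshots}"
        )
    return start, end


def _arrival_and_counts(
    net: TemporalNetwork,
    source_idx: int,
    window: tuple[int, int],
    exclude_idx: int | None = None,
):
    """Earliest arrival steps and time-respecting path counts from a source.

    Walks through the time-expanded DAG: state ``(v, s)`` connects to
    ``(v, s+1)`` (waiting) and to ``(u, s+1)`` for every contact ``u-v`` in
    snapshot ``s+1``.  ``sig[s][v]`` counts distinct contact sequences from
    the source to ``v`` arriving no later than ``s``; the count of
    earliest-arrival paths to ``v`` is ``sig`` evaluated at ``v``'s arrival
    step.  ``exclude_idx`` removes a node as an intermediate (for
    betweenness by path subtraction).

    Returns ``(arrival, sigma_at)`` where ``arrival[v]`` is the arrival
    step (0-based offset from ``start - 1``; -1 when unreached) and
    ``sigma_at`` maps a step offset to the path-count vector at that step.
    """
    start, end = window
    n = net.n_nodes
    arrival = np.full(n, -1, dtype=np.int64)
    arrival[source_idx] = 0
    sig = np.zeros(n)
    sig[source_idx] = 1.0
    sig_history = [sig.copy()]
    for offset, s in enumerate(range(start, end + 1), start=1):
        a = net.snapshot(s, boundary="truncate")
        moved = a @ sig
        new_sig = sig + moved
        if exclude_idx is not None:
            new_sig[exclude_idx] = 0.0
        newly = (arrival < 0) & (new_sig > 0)
        arrival[newly] = offset
        sig = new_sig
        sig_history.append(sig.copy())
    return arrival, sig_history


def temporal_distances(
    net: TemporalNetwork, source: Node, window: tuple[int, int] | None = None
) -> dict[Node, int | None]:
    """Earliest-arrival temporal distances from one source node.

    The distance to ``j`` is ``arrival_step - start + 1`` (so a contact in
    the first window snapshot gives distance 1); unreachable targets map to
    ``None`` and the source to 0.
    """
    if window is None:
        window = (1, net.n_snapshots)
    window = _check_window(net, window)
    if source not in net.node_index:
        raise KeyError(f"unknown source node {source!r}")
    arrival, _ = _arrival_and_counts(net, net.node_index[source], window)
    return {
        u: (int(arrival[i]) if arrival[i] >= 0 else None)
        for i, u in enumerate(net.nodes)
    }


def temporal_distance_table(
    net: TemporalNetwork, window: tuple[int, int] | None = None
) -> TemporalDistanceTable:
    """All-pairs earliest-arrival distances."""
    if window is None:
        window = (1, net.n_snapshots)
    window = _check_window(net, window)
    distances: dict[tuple[Node, Node], int | None] = {}
    for u in net.nodes:
        row = temporal_distances(net, u, window)
        for v, d in row.items():
            distances[(u, v)] = d
    return TemporalDistanceTable(distances=distances, window=window)


def temporal_degree(
    net: TemporalNetwork, window: tuple[int, int] | None = None
) -> CentralityScores:
    """Snapshot degree averaged over the window."""
    if window is None:
        window = (1, net.n_snapshots)
    start, end = _check_window(net, window)
    total = np.zeros(net.n_nodes)
    for s in range(start, end + 1):
        total += np.asarray(net.snapshot(s, "truncate").sum(axis=1)).ravel()
    total /= end - start + 1
    return CentralityScores(
        scores=dict(zip(net.nodes, total.tolist())),
        method="td",
        params={"definition": "window-averaged snapshot degree", "window": window},
    )


def temporal_closeness(
    net: TemporalNetwork, window: tuple[int, int] | None = None
) -> CentralityScores:
    """Sum of reciprocal temporal distances, unreachable contributing 0."""
    if window is None:
        window = (1, net.n_snapshots)
    window = _check_window(net, window)
    scores = {}
    for u in net.nodes:
        row = temporal_distances(net, u, window)
        scores[u] = sum(
            1.0 / d for v, d in row.items() if v != u and d is not None and d > 0
        )
    return CentralityScores(
        scores=scores,
        method="tc",
        params={
            "definition": "sum of reciprocal earliest-arrival distances",
            "window": window,
        },
    )


def temporal_betweenness(
    net: TemporalNetwork, window: tuple[int, int] | None = None
) -> CentralityScores:
    """Earliest-arrival path-count betweenness on the time-ordered graph.

    ``TB_i = sum_{j != k, both != i} sigma_jk(i) / sigma_jk`` over *ordered*
    pairs (temporal reachability is directional), where ``sigma_jk`` counts
    time-respecting contact sequences from ``j`` arriving at ``k`` at its
    earliest arrival step and ``sigma_jk(i)`` those passing through ``i``
    as an intermediate.  Paths through ``i`` are counted by subtraction:
    ``sigma_jk(i) = sigma_jk - sigma_jk`` with ``i`` removed (same arrival
    step required).  Complexity O(N^2 L E) — adequate for its role as a
    baseline on moderate networks.
    """
    if window is None:
        window = (1, net.n_snapshots)
    window = _check_window(net, window)
    n = net.n_nodes
    tb = np.zeros(n)
    for j in range(n):
        arrival, sig_hist = _arrival_and_counts(net, j, window)
        targets = [k for k in range(n) if k != j and arrival[k] > 0]
        if not targets:
            continue
        base_sigma = {k: sig_hist[arrival[k]][k] for k in targets}
        for i in range(n):
            if i == j:
                continue
            _, sig_excl = _arrival_and_counts(net, j, window, exclude_idx=i)
            for k in targets:
                if k == i:
                    continue
                s_all = base_sigma[k]
                s_avoid = sig_excl[arrival[k]][k]
                if s_all > 0:
                    tb[i] += (s_all - s_avoid) / s_all
    return CentralityScores(
        scores=dict(zip(net.nodes, tb.tolist())),
        method="tb",
        params={
            "definition": "earliest-arrival path betweenness, ordered pairs",
            "window": window,
        },
    )
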