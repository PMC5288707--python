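"""Temporal-network data model and I/O.

A temporal network is a fixed node set observed through an ordered sequence
of ``L`` time snapshots of equal width ``delta``.  Each snapshot is a
symmetric binary adjacency matrix ``A(t)`` (``t = 1..L``, 1-based) recording
which pairs were in contact at least once during that time bin.  Contacts
are undirected and unweighted; repeated contacts of a pair within one bin
collapse to a single edge.

The module also provides the static "integrated" view — the element-wise sum
of all snapshots — which discards time order and is the substrate for the
static benchmark centralities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

Node = Hashable

__all__ = [
    "ContactEvent",
    "TemporalNetwork",
    "AggregatedNetwork",
    "ContactListParseError",
    "load_contact_list",
    "write_contact_list",
    "write_snapshots",
    "bin_events",
    "aggregate",
    "snapshot_at",
]


class ContactListParseError(ValueError):
    """Raised when a contact-list file contains a malformed line."""


@dataclass(frozen=True)
class ContactEvent:
    """A single undirected contact between two nodes at a point in time.

    ``(u, v, t)`` and ``(v, u, t)`` denote the same event; self-contacts
    (``u == v``) are invalid and are dropped at parse time.
    """

    u: Node
    v: Node
    time: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-loop contact event on node {self.u!r}")


def _as_binary_symmetric(mat, n: int) -> sparse.csr_matrix:
    m = sparse.csr_matrix(mat, shape=(n, n), dtype=np.float64)
    m.eliminate_zeros()
    data = m.data
    if data.size and not np.all((data == 0) | (data == 1)):
        raise ValueError("snapshot adjacency entries must be 0 or 1")
    if (m != m.T).nnz != 0:
        raise ValueError("snapshot adjacency must be symmetric")
    if m.diagonal().any():
        raise ValueError("snapshot adjacency must have zero diagonal")
    return m


class TemporalNetwork:
    """Node set plus an ordered sequence of binary snapshot adjacencies.

    Parameters
    ----------
    nodes:
        Node identifiers in index order; matrices use this order.
    snapshots:
        Sequence of ``N x N`` symmetric binary matrices (anything scipy can
        coerce); stored internally as CSR.
    delta:
        Snapshot (bin) width in time units.
    t_start:
        Left edge of the first bin; snapshot ``t`` covers
        ``[t_start + (t-1)*delta, t_start + t*delta)``.
    """

    def __init__(
        self,
        nodes: Sequence[Node],
        snapshots: Sequence,
        delta: float = 1.0,
        t_start: float = 0.0,
    ) -> None:
        if len(snapshots) < 1:
            raise ValueError("a temporal network needs at least one snapshot")
        if delta <= 0:
            raise ValueError("delta must be positive")
        self.nodes: list[Node] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        n = len(self.nodes)
        self.snapshots: list[sparse.csr_matrix] = [
            _as_binary_symmetric(a, n) for a in snapshots
        ]
        self.delta = float(delta)
        self.t_start = float(t_start)
        self.node_index: dict[Node, int] = {u: i for i, u in enumerate(self.nodes)}

    # -- basic shape -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def total_time(self) -> float:
        """Total observed span ``T = L * delta``."""
        return self.n_snapshots * self.delta

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TemporalNetwork(N={self.n_nodes}, L={self.n_snapshots}, "
            f"delta={self.delta})"
        )

    # -- snapshot access ---------------------------------------------------
    def snapshot(self, t: int, boundary: str = "truncate") -> sparse.csr_matrix:
        """Return ``A(t)`` for 1-based step ``t``.

        ``boundary='periodic'`` wraps time round the recorded window,
        ``A(L+1) = A(1)``; ``boundary='truncate'`` raises for ``t > L``.
        """
        if t < 1:
            raise IndexError(f"snapshot index must be >= 1, got {t}")
        L = self.n_snapshots
        if boundary == "periodic":
            return self.snapshots[(t - 1) % L]
        if boundary == "truncate":
            if t > L:
                raise IndexError(f"snapshot {t} out of range 1..{L}")
            return self.snapshots[t - 1]
        raise ValueError(f"unknown boundary mode {boundary!r}")

    def edge_lists(self) -> list[list[tuple[Node, Node]]]:
        """Per-snapshot lists of undirected edges ``(u, v)`` with ``u`` first
        in index order."""
        out = []
        for a in self.snapshots:
            coo = sparse.triu(a, k=1).tocoo()
            out.append(
                [(self.nodes[i], self.nodes[j]) for i, j in zip(coo.row, coo.col)]
            )
        return out

    def to_events(self) -> list[ContactEvent]:
        """One event per (pair, snapshot) edge, stamped at the bin midpoint."""
        events = []
        for t, edges in enumerate(self.edge_lists(), start=1):
            mid = self.t_start + (t - 0.5) * self.delta
            events.extend(ContactEvent(u, v, mid) for u, v in edges)
        return events

    def with_snapshots(self, snapshots: Sequence) -> "TemporalNetwork":
        """Copy sharing nodes/delta but with replaced snapshot matrices."""
        return TemporalNetwork(self.nodes, snapshots, self.delta, self.t_start)


@dataclass
class AggregatedNetwork:
    """Static integrated view of a temporal network.

    ``adjacency[i, j]`` counts the snapshots in which the pair was in
    contact; ``binary_adjacency`` marks pairs ever in contact.
    """

    nodes: list[Node]
    adjacency: sparse.csr_matrix
    binary_adjacency: sparse.csr_matrix
    node_index: dict[Node, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {u: i for i, u in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_graph(self):
        """Binary aggregated adjacency as a networkx Graph (all nodes kept)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        coo = sparse.triu(self.binary_adjacency, k=1).tocoo()
        g.add_edges_from(
            (self.nodes[i], self.nodes[j]) for i, j in zip(coo.row, coo.col)
        )
        return g


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_contact_list(path) -> list[ContactEvent]:
    """Parse a whitespace-separated ``u v time`` contact list.

    Lines starting with ``#`` and blank lines are ignored.  Self-loops are
    dropped (with a logged count); duplicate events are preserved; events are
    returned in file order.  An empty file yields an empty list.
    """
    events: list[ContactEvent] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ContactListParseError(
                    f"{path}: line {lineno}: expected 'u v time', got {s!r}"
                )
            u, v = parts[0], parts[1]
            try:
                t = float(parts[2])
            except ValueError as exc:
                raise ContactListParseError(
                    f"{path}: line {lineno}: cannot parse time {parts[2]!r}"
                ) from exc
            if u == v:
                dropped += 1
                continue
            events.append(ContactEvent(u, v, t))
    if dropped:
        logger.info("dropped %d self-loop event(s) while reading %s", dropped, path)
    return events


def write_contact_list(events: Iterable[ContactEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("# u v time\n")
        for e in events:
            fh.write(f"{e.u}\t{e.v}\t{e.time:.10g}\n")


def write_snapshots(net: TemporalNetwork, path) -> None:
    """Dump one ``t u v`` line per (snapshot, edge) with a header carrying
    ``N``, ``L`` and ``delta``."""
    with open(path, "w") as fh:
        fh.write(f"# N={net.n_nodes} L={net.n_snapshots} delta={net.delta:.10g}\n")
        fh.write("# t u v\n")
        for t, edges in enumerate(net.edge_lists(), start=1):
            for u, v in edges:
                fh.write(f"{t}\t{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Binning and aggregation
# ---------------------------------------------------------------------------

def bin_events(
    events: Sequence[ContactEvent],
    delta: float,
    t_start: float = 0.0,
    L: int | None = None,
    nodes: Sequence[Node] | None = None,
) -> TemporalNetwork:
    """Bin timestamped events into ``L`` snapshots of width ``delta``.

    Bins are half-open ``[t_start + (t-1)*delta, t_start + t*delta)``; an
    event falling exactly on the right boundary of the last bin is clamped
    into it.  When ``L`` is omitted it is derived as
    ``ceil((max time - t_start) / delta)`` with a minimum of 1.

    Node identifiers are mapped to dense indices in first-appearance order
    (file order of the events) unless an explicit ``nodes`` list is given.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    for e in events:
        if e.time < t_start:
            raise ValueError(
                f"event {(e.u, e.v, e.time)} precedes t_start={t_start}"
            )
    if L is None:
        if events:
            span = max(e.time for e in events) - t_start
            L = max(1, math.ceil(span / delta))
            if span > 0 and span == L * delta:
                # span exactly on a bin edge: the clamp rule keeps it in bin L
                pass
        else:
            L = 1
    if L < 1:
        raise ValueError("L must be >= 1")

    if nodes is None:
        seen: dict[Node, None] = {}
        for e in events:
            seen.setdefault(e.u)
            seen.setdefault(e.v)
        node_list = list(seen)
    else:
        node_list = list(nodes)
    index = {u: i for i, u in enumerate(node_list)}
    n = len(node_list)

    right_edge = t_start + L * delta
    per_bin: list[set[tuple[int, int]]] = [set() for _ in range(L)]
    for e in events:
        if e.time == right_edge:
            b = L - 1
        else:
            b = int(math.floor((e.time - t_start) / delta))
            if b >= L:
                raise ValueError(
                    f"event at time {e.time} beyond the last bin "
                    f"(t_start={t_start}, delta={delta}, L={L})"
                )
        i, j = index[e.u], index[e.v]
        if i > j:
            i, j = j, i
        per_bin[b].add((i, j))

    snapshots = []
    for pairs in per_bin:
        if pairs:
            rows, cols = zip(*pairs)
            rows = np.fromiter(rows, dtype=np.intp)
            cols = np.fromiter(cols, dtype=np.intp)
            data = np.ones(rows.size, dtype=np.float64)
            a = sparse.coo_matrix(
                (np.concatenate([data, data]),
                 (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                shape=(n, n),
            ).tocsr()
        else:
            a = sparse.csr_matrix((n, n), dtype=np.float64)
        snapshots.append(a)
    return TemporalNetwork(node_list, snapshots, delta=delta, t_start=t_start)


def aggregate(net: TemporalNetwork) -> AggregatedNetwork:
    """Sum snapshots into contact counts and their binary indicator."""
    counts = sparse.csr_matrix((net.n_nodes, net.n_nodes), dtype=np.float64)
    for a in net.snapshots:
        counts = counts + a
    counts = counts.tocsr()
    counts.eliminate_zeros()
    binary = counts.copy()
    binary.data = np.ones_like(binary.data)
    return AggregatedNetwork(list(net.nodes), counts, binary)


def snapshot_at(net: TemporalNetwork, t: int, boundary: str = "periodic"):
    """Module-level alias of :meth:`TemporalNetwork.snapshot`."""
    return net.snapshot(t, boundary=boundary)
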