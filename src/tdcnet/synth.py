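"""Synthetic temporal networks.

``generate_temporal_ba`` emulates a temporal scale-free contact sequence:
``L`` independent Barabási–Albert graphs drawn on one fixed labeled node
set, with the node ordering re-randomized per snapshot so hubs move around
(set ``persistent_hubs=True`` to keep them fixed).  ``generate_temporal_er``
gives homogeneous Erdős–Rényi snapshots for fuzzing, and ``toy_fixture``
returns the small deterministic networks used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .tempnet import TemporalNetwork

__all__ = [
    "GeneratorSpec",
    "generate",
    "generate_temporal_ba",
    "generate_temporal_er",
    "toy_fixture",
]


@dataclass
class GeneratorSpec:
    """Parameters of a synthetic temporal-network draw.

    ``m`` is the BA attachment count (edges per new node; each snapshot then
    has ``m (N - m)`` edges); ``p`` the ER edge probability.
    """

    kind: str
    n: int
    L: int
    m: int = 1
    p: float | None = None
    rng_seed: int = 0
    persistent_hubs: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("temporal_ba", "temporal_er", "toy"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if self.L < 1:
            raise ValueError("need at least 1 snapshot")
        if self.kind == "temporal_ba" and not 1 <= self.m < self.n:
            raise ValueError(f"BA attachment m={self.m} must satisfy 1 <= m < N")
        if self.kind == "temporal_er":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("temporal_er needs edge probability p in [0, 1]")


def _graphs_to_network(graphs, n: int) -> TemporalNetwork:
    snapshots = []
    for g in graphs:
        if g.number_of_edges():
            rows, cols = np.array(g.edges()).T
            d = np.ones(rows.size)
            a = sparse.coo_matrix(
                (np.concatenate([d, d]),
                 (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                shape=(n, n),
            ).tocsr()
        else:
            a = sparse.csr_matrix((n, n))
        snapshots.append(a)
    return TemporalNetwork(list(range(n)), snapshots, delta=1.0)


def generate_temporal_ba(spec: GeneratorSpec) -> TemporalNetwork:
    """L independent BA snapshots on a common node set.

    Unless ``persistent_hubs`` is set, node labels are permuted per snapshot
    so the preferential-attachment hubs land on different nodes each time.
    """
    if spec.kind != "temporal_ba":
        raise ValueError("spec.kind must be 'temporal_ba'")
    rng = np.random.default_rng(spec.rng_seed)
    graphs = []
    for _ in range(spec.L):
        g = nx.barabasi_albert_graph(
            spec.n, spec.m, seed=int(rng.integers(0, 2**31))
        )
        if not spec.persistent_hubs:
            perm = rng.permutation(spec.n)
            g = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(spec.n)})
        graphs.append(g)
    return _graphs_to_network(graphs, spec.n)


def generate_temporal_er(spec: GeneratorSpec) -> TemporalNetwork:
    """L independent G(N, p) snapshots on a common node set."""
    if spec.kind != "temporal_er":
        raise ValueError("spec.kind must be 'temporal_er'")
    rng = np.random.default_rng(spec.rng_seed)
    graphs = [
        nx.fast_gnp_random_graph(spec.n, spec.p, seed=int(rng.integers(0, 2**31)))
        for _ in range(spec.L)
    ]
    return _graphs_to_network(graphs, spec.n)


def generate(spec: GeneratorSpec) -> TemporalNetwork:
    if spec.kind == "temporal_ba":
        return generate_temporal_ba(spec)
    if spec.kind == "temporal_er":
        return generate_temporal_er(spec)
    raise ValueError(f"cannot generate kind {spec.kind!r}")


_TOYS = {
    # 3 nodes, 2 snapshots: A-B then B-C; the canonical hand-checkable chain
    "chain_forward": (["A", "B", "C"], [[("A", "B")], [("B", "C")]]),
    # same contacts in reversed time order: C is unreachable from A
    "chain_reversed": (["A", "B", "C"], [[("B", "C")], [("A", "B")]]),
    # 4 nodes, 3 snapshots — a small fixed multilayer example (synthetic
    # stand-in pattern, not taken from any published figure)
    "fig1_style": (
        ["A", "B", "C", "D"],
        [[("A", "B"), ("C", "D")], [("B", "C")], [("A", "D"), ("B", "D")]],
    ),
}


def toy_fixture(name: str) -> TemporalNetwork:
    """Deterministic toy temporal networks used across the test suite."""
    if name not in _TOYS:
        raise KeyError(f"unknown toy fixture {name!r}; choose from {sorted(_TOYS)}")
    nodes, layers = _TOYS[name]
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    snapshots = []
    for edges in layers:
        a = np.zeros((n, n))
        for u, v in edges:
            a[index[u], index[v]] = 1.0
            a[index[v], index[u]] = 1.0
        snapshots.append(sparse.csr_matrix(a))
    return TemporalNetwork(nodes, snapshots, delta=1.0)
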