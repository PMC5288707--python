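"""Temporal dynamics-sensitive centrality (TDC).

The spreading influence of a node is scored through a linearized
discrete-time SIR Markov chain on the snapshot sequence.  With infection
probability ``beta`` per infectious contact per step and recovery
probability ``mu`` per step, a susceptible node with ``m`` infectious
neighbours is infected with probability approximated as ``m * beta``
(linear coupling).  The expected infectious mass then propagates through
the step matrices

    H(t) = beta * A(t) + (1 - mu) * I,

and the probability of node ``j`` being newly infected at step ``r`` when
``i`` is the sole seed is the ``j`` component of

    P(r) = beta * A(r) . H(r-1) . H(r-2) ... H(1) . x(0),

with ``x(0)`` the indicator of the seed.  The cumulative vector
``x(t) = sum_{r<=t} P(r)`` is an (over-)estimate of the ever-infected
probability — entries may exceed 1; it is used as an influence measure, not
a calibrated probability.  The TDC score of node ``i`` at horizon ``t`` is
the total cumulative mass ``S_i(t) = sum_j x_j(t)``.

Because every ``A(t)`` (hence every ``H(t)``) is symmetric, all ``N`` seed
problems collapse into a single backward sweep:

    S = sum_{r=1}^{t} H(1) H(2) ... H(r-1) (beta * A(r) 1),

which this module evaluates with sparse matrix-vector products only.  With
all snapshots equal the score reduces to the dynamics-sensitive centrality
of static networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tempnet import Node, TemporalNetwork

__all__ = [
    "SpreadingParams",
    "CentralityScores",
    "ProbabilityVectors",
    "PropagatorState",
    "step_matrix",
    "infection_recursion",
    "tdc_scores",
    "normalize_scores",
    "shifted_scores",
]


@dataclass(frozen=True)
class SpreadingParams:
    """Parameters of the (linearized or simulated) SIR dynamics.

    beta:
        Infection probability per infectious contact per step, in [0, 1].
    mu:
        Recovery probability per step, in [0, 1]; ``mu = 0`` gives SI.
    horizon:
        Number of steps ``t >= 1`` the dynamics is run for.
    boundary:
        How steps beyond the recorded window resolve snapshots:
        ``'periodic'`` wraps (``A(L+1) = A(1)``), ``'truncate'`` errors.
    """

    beta: float
    mu: float
    horizon: int
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.boundary not in ("periodic", "truncate"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "mu": self.mu,
            "horizon": self.horizon,
            "boundary": self.boundary,
        }


@dataclass
class CentralityScores:
    """Per-node real-valued scores with method metadata."""

    scores: dict[Node, float]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for node {u!r}")

    def vector(self, nodes: Sequence[Node] | None = None) -> np.ndarray:
        order = list(self.scores) if nodes is None else list(nodes)
        return np.array([self.scores[u] for u in order], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"node": list(self.scores), "score": list(self.scores.values())}
        )
        df["method"] = self.method
        for k in ("beta", "mu", "horizon"):
            if k in self.params:
                df[k] = self.params[k]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ProbabilityVectors:
    """Trajectory of the linearized infection recursion for one seed.

    ``newly[r-1]`` is ``P(r)``, the expected newly-infected mass at step
    ``r``; ``cumulative[r-1]`` is ``x(r) = sum_{s<=r} P(s)``.  Entries are
    nonnegative and cumulative entries may exceed 1 by construction.
    """

    x0: np.ndarray
    newly: np.ndarray  # shape (horizon, N)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.newly, axis=0)

    @property
    def final(self) -> np.ndarray:
        """``x(horizon)``."""
        return self.newly.sum(axis=0)


def step_matrix(net: TemporalNetwork, t: int, params: SpreadingParams):
    """One-step propagator ``H(t) = beta * A(t) + (1 - mu) * I`` (sparse)."""
    from scipy import sparse

    a = net.snapshot(t, boundary=params.boundary)
    return (params.beta * a + (1.0 - params.mu) * sparse.identity(
        net.n_nodes, format="csr"
    )).tocsr()


@dataclass
class PropagatorState:
    """Dense step matrices ``H(t)`` and chronological left products
    ``H^(r) = H(r) . H(r-1) ... H(1)`` with ``H^(0) = I``.

    Materializes ``horizon + 1`` dense ``N x N`` matrices — intended for
    verification and small networks; the production score path never builds
    these products.
    """

    step_matrices: list[np.ndarray]
    left_products: list[np.ndarray]

    @classmethod
    def build(
        cls, net: TemporalNetwork, params: SpreadingParams, horizon: int | None = None
    ) -> "PropagatorState":
        t_max = params.horizon if horizon is None else horizon
        steps = []
        prods = [np.eye(net.n_nodes)]
        for r in range(1, t_max + 1):
            h = step_matrix(net, r, params).toarray()
            steps.append(h)
            prods.append(h @ prods[-1])
        return cls(steps, prods)


def infection_recursion(
    net: TemporalNetwork, seed: Node, params: SpreadingParams
) -> ProbabilityVectors:
    """Run the linearized SIR recursion from a single seed.

    Computed stepwise through the infectious-mass vector
    ``y(r) = H(r) y(r-1)``, ``y(0) = x(0)``; ``P(r) = beta A(r) y(r-1)``.
    This is algebraically identical to the closed form
    ``P(r) = beta A(r) H^(r-1) x(0)``.
    """
    if seed not in net.node_index:
        raise KeyError(f"unknown seed node {seed!r}")
    n = net.n_nodes
    x0 = np.zeros(n)
    x0[net.node_index[seed]] = 1.0
    beta, mu = params.beta, params.mu
    y = x0.copy()
    newly = np.empty((params.horizon, n))
    for r in range(1, params.horizon + 1):
        a = net.snapshot(r, boundary=params.boundary)
        p = beta * (a @ y)
        newly[r - 1] = p
        y = p + (1.0 - mu) * y
    return ProbabilityVectors(x0=x0, newly=newly)


def tdc_scores(
    net: TemporalNetwork, params: SpreadingParams, method: str = "onepass"
) -> CentralityScores:
    """Temporal dynamics-sensitive centrality of every node.

    ``method='onepass'`` (default) evaluates the transposed closed form with
    one backward sweep of sparse matrix-vector products; ``method='perseed'``
    runs the recursion once per seed node.  Both agree to floating-point
    tolerance and the equivalence is asserted in the test suite.
    """
    beta, mu, t = params.beta, params.mu, params.horizon
    n = net.n_nodes
    if method == "perseed":
        s = np.array(
            [
                infection_recursion(net, u, params).final.sum()
                for u in net.nodes
            ]
        )
    elif method == "onepass":
        # S = sum_r H(1)...H(r-1) (beta A(r) 1), accumulated backwards:
        # acc_r = u_r + H(r) acc_{r+1}
        ones = np.ones(n)
        acc = np.zeros(n)
        for r in range(t, 0, -1):
            a = net.snapshot(r, boundary=params.boundary)
            acc = beta * (a @ ones) + beta * (a @ acc) + (1.0 - mu) * acc
        s = acc
    else:
        raise ValueError(f"unknown method {method!r}")
    return CentralityScores(
        scores=dict(zip(net.nodes, s.tolist())),
        method="tdc",
        params=params.as_dict(),
    )


def normalize_scores(scores: CentralityScores) -> CentralityScores:
    """Min-max rescale scores to [0, 1], preserving order.

    A constant score vector maps to all zeros.
    """
    if not scores.scores:
        raise ValueError("cannot normalize an empty score vector")
    v = scores.vector()
    lo, hi = v.min(), v.max()
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return CentralityScores(
        scores=dict(zip(scores.scores, out.tolist())),
        method=scores.method + "_normalized",
        params=dict(scores.params),
    )


def shifted_scores(scores: CentralityScores) -> CentralityScores:
    """Add 1 to each score — plotting convenience for sharing an axis with
    normalized simulation output."""
    return CentralityScores(
        scores={u: s + 1.0 for u, s in scores.scores.items()},
        method=scores.method + "_shifted",
        params=dict(scores.params),
    )
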