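"""Epidemic threshold of a temporal network via the infection propagator.

Under periodic boundary conditions the linearized SIR dynamics over one full
period of ``L`` snapshots is governed by the chronological product

    M = H(L) . H(L-1) ... H(1),      H(t) = beta * A(t) + (1 - mu) * I.

The infection dies out when the spectral radius ``rho(M) < 1`` and grows
when ``rho(M) > 1``; the epidemic threshold ``beta_c`` solves
``rho(M(beta)) = 1``.  All factors are entrywise nonnegative, so ``rho`` is
a real eigenvalue, is nondecreasing in ``beta``, and the threshold is found
by bisection.

The product ``M`` is never formed: power iteration applies the ``L`` sparse
factors to a vector in sequence, renormalizing after each factor and
accumulating log-growth, which keeps the computation stable even when
``rho(M)`` would overflow a double.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .tempnet import TemporalNetwork, aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdResult",
    "PowerIterationError",
    "propagator_spectral_radius",
    "epidemic_threshold",
]


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge; carries the last estimate."""

    def __init__(self, message: str, estimate: float):
        super().__init__(message)
        self.estimate = estimate


@dataclass
class ThresholdResult:
    """Solution of ``rho(M(beta)) = 1``."""

    beta_c: float
    mu: float
    rho_at_beta_c: float
    iterations: int
    bracket: tuple[float, float]


def _log_spectral_radius(
    net: TemporalNetwork,
    beta: float,
    mu: float,
    tol: float = 1e-10,
    max_sweeps: int = 100_000,
) -> float:
    """``log rho(M)`` by power iteration over the L-factor product.

    Deterministic all-ones start; per-sweep growth is accumulated on the log
    scale.  Returns ``-inf`` when the iterate is annihilated (``rho = 0``).
    """
    n = net.n_nodes
    snaps = net.snapshots
    decay = 1.0 - mu
    v = np.full(n, 1.0 / math.sqrt(n))
    log_lam_prev = None
    for sweep in range(1, max_sweeps + 1):
        log_growth = 0.0
        for a in snaps:
            v = beta * (a @ v) + decay * v
            nv = np.linalg.norm(v)
            if nv == 0.0:
                return -math.inf
            log_growth += math.log(nv)
            v = v / nv
        if log_lam_prev is not None and abs(log_growth - log_lam_prev) <= tol:
            return log_growth
        log_lam_prev = log_growth
    raise PowerIterationError(
        f"power iteration did not converge in {max_sweeps} sweeps",
        estimate=math.exp(log_lam_prev),
    )


def propagator_spectral_radius(
    net: TemporalNetwork,
    beta: float,
    mu: float,
    tol: float = 1e-10,
    max_sweeps: int = 100_000,
) -> float:
    """Spectral radius of the one-period infection propagator ``M``.

    May overflow to ``inf`` for strongly supercritical parameters; the
    threshold solver works on the log scale and is unaffected.
    """
    if not 0.0 <= beta <= 1.0 or not 0.0 <= mu <= 1.0:
        raise ValueError("beta and mu must lie in [0, 1]")
    log_rho = _log_spectral_radius(net, beta, mu, tol=tol, max_sweeps=max_sweeps)
    try:
        return math.exp(log_rho)
    except OverflowError:  # pragma: no cover - extreme parameters
        return math.inf


def epidemic_threshold(
    net: TemporalNetwork,
    mu: float,
    tol: float = 1e-6,
    beta_max: float = 1.0,
    power_tol: float = 1e-10,
) -> ThresholdResult:
    """Solve ``rho(M(beta)) = 1`` for ``beta_c`` by bisection on [0, beta_max].

    Monotonicity of ``rho`` in ``beta`` (entrywise-monotone nonnegative
    factors) guarantees the bisection is valid.  Raises ``ValueError`` when
    no threshold exists below ``beta_max``; for ``mu = 0`` the dynamics
    never dies out and ``beta_c = 0`` is returned with a warning.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    agg = aggregate(net)
    if agg.binary_adjacency.nnz == 0:
        raise ValueError("network has no contacts; threshold undefined")
    import networkx as nx

    g = agg.to_graph()
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        warnings.warn(
            f"aggregated network has {len(comps)} components; rho(M) is the "
            "maximum over components",
            stacklevel=2,
        )

    if mu == 0.0:
        warnings.warn(
            "mu = 0: rho(M(0)) = 1 already; returning beta_c = 0",
            stacklevel=2,
        )
        return ThresholdResult(
            beta_c=0.0, mu=mu, rho_at_beta_c=1.0, iterations=0, bracket=(0.0, 0.0)
        )

    log_rho_hi = _log_spectral_radius(net, beta_max, mu, tol=power_tol)
    if log_rho_hi < 0.0:
        raise ValueError(
            f"rho(M) = {math.exp(log_rho_hi):.6g} < 1 at beta = {beta_max}: "
            "no epidemic threshold in range"
        )

    lo, hi = 0.0, beta_max
    iterations = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        iterations += 1
        if _log_spectral_radius(net, mid, mu, tol=power_tol) >= 0.0:
            hi = mid
        else:
            lo = mid
    beta_c = 0.5 * (lo + hi)
    rho = propagator_spectral_radius(net, beta_c, mu, tol=power_tol)
    return ThresholdResult(
        beta_c=beta_c,
        mu=mu,
        rho_at_beta_c=rho,
        iterations=iterations,
        bracket=(lo, hi),
    )
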