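"""Ranking evaluation: Kendall tau agreement and the two experiment
pipelines (centrality methods vs simulated influence; time-order impact
across a (mu, beta) grid).

Kendall's tau-b (tie-corrected) is used throughout: simulation means at
modest run counts produce ties, and tau is invariant to any strictly
monotone rescaling of either ranking, which is why all centrality scores
are compared unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import benchmarks
from .nullmodel import null_ensemble_influence
from .sir_sim import spreading_influence
from .tdc_core import CentralityScores, SpreadingParams, tdc_scores
from .tempnet import TemporalNetwork, aggregate

__all__ = [
    "TauResult",
    "ExperimentGrid",
    "kendall_tau",
    "method_comparison",
    "time_order_impact",
    "STRUCTURAL_METHODS",
]

STRUCTURAL_METHODS = ("sd", "td", "sc", "tc", "sb", "tb")


@dataclass
class TauResult:
    """Kendall rank correlation between two score vectors."""

    tau: float
    n: int
    method_a: str
    method_b: str


@dataclass
class ExperimentGrid:
    """Parameter grid shared by the evaluation experiments.

    ``runs`` controls the SIR reference in the method comparison;
    ``n_shuffles`` the null-model ensemble in the time-order experiment.
    Defaults are desk-scale; raise them towards 10^4 runs / 10^3 shuffles
    to match full-scale experiments.
    """

    mu_values: Sequence[float]
    beta_values: Sequence[float]
    horizon: int
    runs: int = 1000
    n_shuffles: int = 100
    sweeps: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not len(self.mu_values) or not len(self.beta_values):
            raise ValueError("mu_values and beta_values must be non-empty")
        for r in list(self.mu_values) + list(self.beta_values):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


def kendall_tau(a: CentralityScores, b: CentralityScores) -> TauResult:
    """Tie-corrected Kendall tau-b between two score vectors paired by node.

    Raises ``ValueError`` naming the offending side when either vector is
    constant (tau undefined).
    """
    if set(a.scores) != set(b.scores):
        raise ValueError("score vectors cover different node sets")
    nodes = list(a.scores)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes for a rank correlation")
    va = a.vector(nodes)
    vb = b.vector(nodes)
    if np.all(va == va[0]):
        raise ValueError(f"tau undefined: all {a.method!r} scores identical")
    if np.all(vb == vb[0]):
        raise ValueError(f"tau undefined: all {b.method!r} scores identical")
    tau, _ = stats.kendalltau(va, vb)
    return TauResult(tau=float(tau), n=len(nodes), method_a=a.method, method_b=b.method)


def _structural_scores(net: TemporalNetwork, methods, window) -> dict[str, CentralityScores]:
    agg = aggregate(net)
    out: dict[str, CentralityScores] = {}
    for m in methods:
        if m == "sd":
            out[m] = benchmarks.static_degree(agg)
        elif m == "sc":
            out[m] = benchmarks.static_closeness(agg)
        elif m == "sb":
            out[m] = benchmarks.static_betweenness(agg)
        elif m == "td":
            out[m] = benchmarks.temporal_degree(net, window)
        elif m == "tc":
            out[m] = benchmarks.temporal_closeness(net, window)
        elif m == "tb":
            out[m] = benchmarks.temporal_betweenness(net, window)
    return out


def method_comparison(
    net: TemporalNetwork,
    grid: ExperimentGrid,
    methods: Sequence[str] = STRUCTURAL_METHODS + ("tdc",),
    reference: Callable[[TemporalNetwork, SpreadingParams], CentralityScores] | None = None,
) -> pd.DataFrame:
    """Rank agreement of each centrality method with simulated SIR influence.

    For each ``(mu, beta)`` grid cell the SIR reference ranking is the mean
    influence over ``grid.runs`` runs per seed; structural methods are
    computed once (they do not depend on the dynamics) while the TDC score
    is recomputed per cell.  ``reference`` may replace the SIR simulation
    with any callable returning a :class:`CentralityScores` (used by tests).

    Returns a tidy frame with columns mu, beta, method, tau, n.
    """
    unknown = set(methods) - set(STRUCTURAL_METHODS) - {"tdc"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    window = (1, min(grid.horizon, net.n_snapshots))
    structural = _structural_scores(
        net, [m for m in methods if m in STRUCTURAL_METHODS], window
    )
    rows = []
    for mu in grid.mu_values:
        for i, beta in enumerate(grid.beta_values):
            params = SpreadingParams(beta=beta, mu=mu, horizon=grid.horizon)
            if reference is None:
                cell_seed = np.random.SeedSequence(
                    grid.rng_seed, spawn_key=(int(round(mu * 1e6)), i)
                ).generate_state(1)[0] % (2**31)
                ref, _ = spreading_influence(net, params, grid.runs, int(cell_seed))
            else:
                ref = reference(net, params)
            for m in methods:
                scores = tdc_scores(net, params) if m == "tdc" else structural[m]
                t = kendall_tau(scores, ref)
                rows.append(
                    {"mu": mu, "beta": beta, "method": m, "tau": t.tau, "n": t.n}
                )
    return pd.DataFrame(rows)


def time_order_impact(
    net: TemporalNetwork, grid: ExperimentGrid
) -> pd.DataFrame:
    """Impact of time-order on spreading influence across a (mu, beta) grid.

    Per cell: ``S`` is the TDC score of the original network, ``S'`` the
    mean TDC over ``grid.n_shuffles`` time-shuffled replicas; the reported
    tau compares ``S`` with ``S'`` (larger tau = smaller impact of time
    order).  ``dispersion`` is two standard deviations of the per-shuffle
    taus ``tau(S, S_k)``.

    Returns a tidy frame with columns mu, beta, tau, dispersion,
    n_shuffles.  The horizon is typically set to ``L`` so the dynamics
    covers the full recorded window once.
    """
    rows = []
    for mu in grid.mu_values:
        for i, beta in enumerate(grid.beta_values):
            params = SpreadingParams(beta=beta, mu=mu, horizon=grid.horizon)
            s_orig = tdc_scores(net, params)
            cell_seed = int(
                np.random.SeedSequence(
                    grid.rng_seed, spawn_key=(int(round(mu * 1e6)), i)
                ).generate_state(1)[0]
                % (2**31)
            )
            s_null, samples = null_ensemble_influence(
                net,
                params,
                n_shuffles=grid.n_shuffles,
                rng_seed=cell_seed,
                sweeps=grid.sweeps,
                return_samples=True,
            )
            tau = kendall_tau(s_orig, s_null).tau
            v_orig = s_orig.vector(net.nodes)
            per_shuffle = []
            for k in range(samples.shape[0]):
                t, _ = stats.kendalltau(v_orig, samples[k])
                per_shuffle.append(t)
            per_shuffle = np.asarray(per_shuffle, dtype=float)
            dispersion = (
                2.0 * float(np.nanstd(per_shuffle, ddof=1))
                if len(per_shuffle) > 1
                else 0.0
            )
            rows.append(
                {
                    "mu": mu,
                    "beta": beta,
                    "tau": tau,
                    "dispersion": dispersion,
                    "n_shuffles": grid.n_shuffles,
                }
            )
    return pd.DataFrame(rows)
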