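"""Discrete-time Monte Carlo SIR on a temporal network.

One node starts infectious; at step ``s`` (resolved to snapshot ``A(s)``,
periodically when the horizon exceeds the recorded window):

1. every susceptible node with ``k`` infectious neighbours becomes infected
   with probability ``1 - (1 - beta)^k`` (independent Bernoulli trial per
   infectious contact — the exact nonlinear coupling, unlike the linearized
   analytic score);
2. every node infectious at the *start* of the step recovers with
   probability ``mu`` (newly infected nodes cannot recover in the step they
   are infected and become infectious at the next step).

The spreading influence ``N_i(t)`` of seed ``i`` is the number of
ever-infected nodes (states I or R, seed included) after ``t`` steps,
averaged over independent runs.

Randomness is drawn from counter-based substreams keyed by
``(rng_seed, seed-node index, replicate index)``, so per-seed results are
reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tdc_core import CentralityScores, SpreadingParams
from .tempnet import Node, TemporalNetwork

__all__ = [
    "SimulationResult",
    "run_sir",
    "ever_infected_probabilities",
    "spreading_influence",
]


@dataclass
class SimulationResult:
    """Monte Carlo summary of one seed's spreading influence."""

    seed: Node
    runs: int
    mean_influence: float
    std_influence: float
    horizon: int
    params: SpreadingParams


def _substream(rng_seed: int, node_idx: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(node_idx, replicate))
    )


def _resolve_snapshots(net: TemporalNetwork, params: SpreadingParams):
    return [
        net.snapshot(s, boundary=params.boundary)
        for s in range(1, params.horizon + 1)
    ]


def _single_run(snaps, n: int, seed_idx: int, beta: float, mu: float,
                rng: np.random.Generator) -> np.ndarray:
    """One SIR realization; returns the boolean ever-infected mask."""
    infectious = np.zeros(n, dtype=bool)
    infectious[seed_idx] = True
    susceptible = ~infectious
    for a in snaps:
        k = a @ infectious.astype(np.float64)
        p_inf = np.where(k > 0, 1.0 - (1.0 - beta) ** k, 0.0)
        u_inf = rng.random(n)
        u_rec = rng.random(n)
        newly = susceptible & (u_inf < p_inf)
        recovered_now = infectious & (u_rec < mu)
        infectious = (infectious & ~recovered_now) | newly
        susceptible &= ~newly
    return ~susceptible


def run_sir(
    net: TemporalNetwork,
    seed: Node,
    params: SpreadingParams,
    rng_seed: int,
    replicate: int = 0,
) -> int:
    """Single SIR run; returns the ever-infected count (>= 1)."""
    if seed not in net.node_index:
        raise KeyError(f"unknown seed node {seed!r}")
    idx = net.node_index[seed]
    snaps = _resolve_snapshots(net, params)
    rng = _substream(rng_seed, idx, replicate)
    mask = _single_run(snaps, net.n_nodes, idx, params.beta, params.mu, rng)
    return int(mask.sum())


def ever_infected_probabilities(
    net: TemporalNetwork,
    seed: Node,
    params: SpreadingParams,
    runs: int,
    rng_seed: int,
) -> np.ndarray:
    """Per-node Monte Carlo frequency of ever being infected from ``seed``."""
    if seed not in net.node_index:
        raise KeyError(f"unknown seed node {seed!r}")
    idx = net.node_index[seed]
    snaps = _resolve_snapshots(net, params)
    n = net.n_nodes
    freq = np.zeros(n)
    for rep in range(runs):
        rng = _substream(rng_seed, idx, rep)
        freq += _single_run(snaps, n, idx, params.beta, params.mu, rng)
    return freq / runs


def simulate_node(
    net: TemporalNetwork,
    seed: Node,
    params: SpreadingParams,
    runs: int,
    rng_seed: int,
) -> SimulationResult:
    """Mean and standard deviation of the influence of one seed."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    idx = net.node_index[seed]
    snaps = _resolve_snapshots(net, params)
    n = net.n_nodes
    counts = np.empty(runs)
    for rep in range(runs):
        rng = _substream(rng_seed, idx, rep)
        counts[rep] = _single_run(snaps, n, idx, params.beta, params.mu, rng).sum()
    return SimulationResult(
        seed=seed,
        runs=runs,
        mean_influence=float(counts.mean()),
        std_influence=float(counts.std(ddof=1)) if runs > 1 else 0.0,
        horizon=params.horizon,
        params=params,
    )


def spreading_influence(
    net: TemporalNetwork,
    params: SpreadingParams,
    runs: int,
    rng_seed: int,
) -> tuple[CentralityScores, dict[Node, SimulationResult]]:
    """Mean SIR influence of every node over ``runs`` replicates each."""
    results = {
        u: simulate_node(net, u, params, runs, rng_seed) for u in net.nodes
    }
    scores = CentralityScores(
        scores={u: r.mean_influence for u, r in results.items()},
        method="sir",
        params={**params.as_dict(), "runs": runs, "rng_seed": rng_seed},
    )
    return scores, results
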