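"""Independent reference implementations used as test oracles.

Everything here is deliberately literal — dense matrices, explicit matrix
powers, exhaustive enumeration — and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def dense_snapshots(net):
    return [a.toarray() for a in net.snapshots]


def closed_form_newly_infected(snaps, seed_idx, beta, mu, horizon, periodic=True):
    """P(r) = beta A(r) H^(r-1) x(0) evaluated with literal dense products."""
    n = snaps[0].shape[0]
    L = len(snaps)
    x0 = np.zeros(n)
    x0[seed_idx] = 1.0
    eye = np.eye(n)
    h_prod = eye.copy()  # H^(0)
    out = []
    for r in range(1, horizon + 1):
        a = snaps[(r - 1) % L] if periodic else snaps[r - 1]
        out.append(beta * a @ h_prod @ x0)
        h = beta * a + (1.0 - mu) * eye
        h_prod = h @ h_prod
    return np.array(out)


def closed_form_scores(snaps, beta, mu, horizon, periodic=True):
    """S_i = sum_j x_j(horizon) from the dense closed form, seed by seed."""
    n = snaps[0].shape[0]
    return np.array(
        [
            closed_form_newly_infected(snaps, i, beta, mu, horizon, periodic)
            .sum()
            for i in range(n)
        ]
    )


def liu_static_dsc(adj, beta, mu, horizon):
    """Dynamics-sensitive centrality of a static network: literal evaluation
    of S = sum_{r=1}^{t} [(beta A) H^(r-1)]^T 1 with H = beta A + (1-mu) I."""
    n = adj.shape[0]
    h = beta * adj + (1.0 - mu) * np.eye(n)
    ones = np.ones(n)
    s = np.zeros(n)
    for r in range(1, horizon + 1):
        s += (beta * adj @ np.linalg.matrix_power(h, r - 1)).T @ ones
    return s


def dense_propagator_rho(snaps, beta, mu):
    """Spectral radius of the explicitly multiplied one-period propagator."""
    n = snaps[0].shape[0]
    m = np.eye(n)
    for a in snaps:  # chronological: M = H(L) ... H(1)
        m = (beta * a + (1.0 - mu) * np.eye(n)) @ m
    return float(max(abs(np.linalg.eigvals(m))))


def brute_kendall_tau_b(x, y):
    """O(n^2) tie-corrected Kendall tau-b by explicit pair enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0:
                ties_x += 1
            if dy == 0:
                ties_y += 1
            if dx != 0 and dy != 0:
                if dx * dy > 0:
                    nc += 1
                else:
                    nd += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (nc - nd) / denom


def enumerate_earliest_arrival_paths(snaps, source, window):
    """Exhaustively enumerate time-respecting contact sequences from a node.

    Returns ``(arrival, paths)`` where ``arrival[k]`` is the earliest step
    offset at which ``k`` is reached (-1 if never) and ``paths[k]`` lists,
    for each earliest-arrival walk, the tuple of intermediate nodes visited
    (excluding source and target).  A walk is a choice, at each step of the
    window, of either waiting or moving along an edge of that snapshot; a
    walk "reaches k" when its final move lands on k.
    """
    start, end = window
    n = snaps[0].shape[0]
    landings: dict[int, list[tuple[int, tuple[int, ...]]]] = {
        k: [] for k in range(n)
    }

    def rec(node, step, visited):
        if step > end:
            return
        a = snaps[step - 1]
        for nb in np.nonzero(a[node])[0]:
            nb = int(nb)
            landings[nb].append((step - start + 1, tuple(visited)))
            rec(nb, step + 1, visited + [nb])
        rec(node, step + 1, visited)  # wait

    rec(source, start, [])
    arrival = {k: -1 for k in range(n)}
    arrival[source] = 0
    paths: dict[int, list[tuple[int, ...]]] = {}
    for k in range(n):
        if k == source:
            paths[k] = []
            continue
        offsets = [off for off, _ in landings[k]]
        if not offsets:
            paths[k] = []
            continue
        arrival[k] = min(offsets)
        paths[k] = [
            inter for off, inter in landings[k] if off == arrival[k]
        ]
    return arrival, paths


def brute_temporal_betweenness(snaps, window):
    """TB_i over ordered pairs by exhaustive walk enumeration.

    For each earliest-arrival walk to k, the intermediate nodes are the
    nodes landed on before the final landing (the target never appears
    there — an earlier landing on it would contradict earliest arrival).
    """
    n = snaps[0].shape[0]
    tb = np.zeros(n)
    for j in range(n):
        arrival, paths = enumerate_earliest_arrival_paths(snaps, j, window)
        for k in range(n):
            if k == j or not paths[k]:
                continue
            sigma = len(paths[k])
            for i in range(n):
                if i in (j, k):
                    continue
                through = sum(1 for inter in paths[k] if i in inter)
                tb[i] += through / sigma
    return tb


def exact_chain_sir_means(beta, mu):
    """Expected ever-infected counts on the forward chain (A-B then B-C),
    horizon 2, by exact enumeration of the update order:
    infect from start-of-step infectious set, then recover."""
    e_a = 1 + beta + beta * beta
    e_b = 1 + beta + (1 - mu) * beta
    e_c = 1 + (1 - mu) * beta
    return {"A": e_a, "B": e_b, "C": e_c}
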