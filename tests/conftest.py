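import sys
from pathlib import Path

import numpy as np
import pytest
from scipy import sparse

from tdcnet import GeneratorSpec, SpreadingParams, TemporalNetwork
from tdcnet.synth import generate_temporal_er, toy_fixture

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def chain_forward():
    """A-B in snapshot 1, B-C in snapshot 2."""
    return toy_fixture("chain_forward")


@pytest.fixture
def chain_reversed():
    """B-C in snapshot 1, A-B in snapshot 2."""
    return toy_fixture("chain_reversed")


@pytest.fixture
def chain_params():
    return SpreadingParams(beta=0.1, mu=0.1, horizon=2)


@pytest.fixture
def star_all_snapshots():
    """Star with 4 leaves, every pair connected in every snapshot — no empty
    slot for any pair, so time-shuffling is a no-op."""
    n = 5
    a = np.zeros((n, n))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return TemporalNetwork(list("CABDE"), [sparse.csr_matrix(a)] * 4)


def random_er_network(rng, n_max=50, l_max=20, n_min=3, l_min=2):
    """Random temporal ER instance for fuzzing."""
    n = int(rng.integers(n_min, n_max + 1))
    L = int(rng.integers(l_min, l_max + 1))
    p = float(rng.uniform(0.05, 0.4))
    spec = GeneratorSpec(
        kind="temporal_er", n=n, L=L, p=p, rng_seed=int(rng.integers(2**31))
    )
    return generate_temporal_er(spec)


def make_network(nodes, layers, delta=1.0):
    """Build a TemporalNetwork from per-snapshot edge lists."""
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    snaps = []
    for edges in layers:
        a = np.zeros((n, n))
        for u, v in edges:
            a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        snaps.append(sparse.csr_matrix(a))
    return TemporalNetwork(nodes, snaps, delta=delta)
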