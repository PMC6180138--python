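import numpy as np
import pandas as pd
import pytest

from empathnet import IsingNetwork, load_instrument_specs

#: Desk-scale fit settings for permutation-heavy simulations: a shorter
#: penalty path gives near-identical EBIC selections at a fraction of the cost.
FAST_FIT = {"n_lambdas": 25, "lambda_min_ratio": 0.05}


@pytest.fixture(scope="session")
def specs():
    return load_instrument_specs()


def chain_model(p=6, beta=1.0, tau=-0.5, labels=None):
    """Ising chain: couplings beta on consecutive pairs, constant thresholds."""
    w = np.zeros((p, p))
    for i in range(p - 1):
        w[i, i + 1] = w[i + 1, i] = beta
    labels = labels or [f"n{i}" for i in range(p)]
    return IsingNetwork(tuple(labels), w, np.full(p, float(tau)))


def triangle_pair_weights():
    """Two disconnected unit-weight triangles on 6 nodes."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return w


def planted_clustering_model(beta=1.2, tau=-0.6):
    """6-node model with triangles 0-1-2 and 1-2-3 plus a 3-4-5 tail.

    Removing node 0's edges between time points destroys its (high) local
    clustering while the 1-2-3 triangle keeps the neighbours clustered.
    """
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4), (4, 5)]:
        w[a, b] = w[b, a] = beta
    return IsingNetwork(tuple(f"n{i}" for i in range(6)), w, np.full(6, float(tau)))


def clique_tail_model(beta=1.2, tau_clique=-1.8, tau_tail=-0.8):
    """6-node model: a 4-clique on nodes 0-3 plus a 3-4-5 tail.

    Isolating node 0 between time points destroys its (dense) local
    clustering; the clique keeps the estimate graded rather than 0/1 when
    single edges drop out of a refit.
    """
    import itertools

    w = np.zeros((6, 6))
    for a, b in itertools.combinations(range(4), 2):
        w[a, b] = w[b, a] = beta
    for a, b in [(3, 4), (4, 5)]:
        w[a, b] = w[b, a] = beta
    t = np.full(6, float(tau_tail))
    t[:4] = tau_clique
    return IsingNetwork(tuple(f"n{i}" for i in range(6)), w, t)


def random_weight_matrix(rng, n, density=0.5, wmin=0.1, wmax=1.0):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(wmin, wmax, size=len(iu[0]))
    w[iu] = np.where(mask, vals, 0.0)
    return w + w.T


def likert_table(specs, rows):
    """Build a Likert response table from {column: values} plus default meta."""
    n = len(next(iter(rows.values())))
    data = {
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "time_point": ["PRE"] * n,
    }
    data.update(rows)
    return pd.DataFrame(data)
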