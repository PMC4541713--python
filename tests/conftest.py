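import itertools

import numpy as np
import pytest

from idiotopo import CouplingModel, energy


@pytest.fixture
def pair_model():
    """N=2, S=0, single coupling J=0.5."""
    return CouplingModel(N=2, S=0.0, pairwise=np.array([[0, 0.5], [0.5, 0]]))


@pytest.fixture
def flip_flop_model():
    """N=2, S=-0.5, J_12=1: period-2 oscillator with a (1,1) fixed point."""
    return CouplingModel(N=2, S=-0.5, pairwise=np.array([[0, 1.0], [1.0, 0]]))


def random_pairwise_model(rng, N, edge_prob=0.5, S=0.0):
    J = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if rng.random() < edge_prob:
                J[i, j] = J[j, i] = rng.uniform(-1, 1)
    return CouplingModel(N=N, S=S, pairwise=J)


def naive_partition(model, complex, x):
    """Independent brute-force oracle: explicit loop over all valuations."""
    Z = 0.0
    for c in itertools.product((0, 1), repeat=model.N):
        Z += np.exp(-x * energy(np.array(c), model, complex))
    return Z


def naive_correlation(model, complex, x, indices):
    num = 0.0
    den = 0.0
    for c in itertools.product((0, 1), repeat=model.N):
        w = np.exp(-x * energy(np.array(c), model, complex))
        den += w
        if all(c[i] == 1 for i in indices):
            num += w
    return num / den
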