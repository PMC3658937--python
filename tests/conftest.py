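import numpy as np
import pytest

from pairedbb.data_model import (
    ModelSpec,
    PairedCountMatrix,
    ReplicateStructure,
    ScalingFactors,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """Five tuples x four sample pairs, including one all-zero tuple."""
    first = np.array([
        [10, 12, 9, 11],
        [30, 28, 31, 29],
        [0, 0, 0, 0],
        [5, 0, 2, 1],
        [100, 90, 110, 95],
    ])
    second = np.array([
        [10, 11, 10, 12],
        [10, 12, 9, 11],
        [0, 0, 0, 0],
        [0, 3, 1, 2],
        [25, 30, 28, 27],
    ])
    return PairedCountMatrix(
        [f"g{i}" for i in range(5)], first, second, ["p1", "p2", "p3", "p4"])


@pytest.fixture
def unit_scaling():
    return ScalingFactors.unit(4)


@pytest.fixture
def one_group():
    return ReplicateStructure.single_group(4)


@pytest.fixture
def model_pair():
    null = ModelSpec("no_de", [[0, 1, 2, 3]], [0.5])
    free = ModelSpec("consistent_de", [[0, 1, 2, 3]], [None])
    return [null, free]


def sample_beta_binomial(rng, n, pi, phi, depth=500, L=None, L_prime=None):
    """Direct compound draws: N ~ Poisson(depth), M ~ Beta, u ~ Binom(N, M)."""
    from pairedbb.betabinom import effective_proportion

    L = np.ones(n) if L is None else L
    L_prime = np.ones(n) if L_prime is None else L_prime
    p = effective_proportion(pi, L, L_prime)
    N = rng.poisson(depth, n)
    if phi == 0:
        u = rng.binomial(N, p)
    else:
        a = p * (1 - phi) / phi
        b = (1 - p) * (1 - phi) / phi
        u = rng.binomial(N, rng.beta(a, b, n))
    return u, N - u
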