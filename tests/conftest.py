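import numpy as np
import pytest

from hcynet.dataset import CategoricalDataset, VariableSpec

from oracles import binary_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230128)


@pytest.fixture(scope="session")
def xor_dataset():
    """Parity trap: C = A xor B with 10% flips, D independent.

    No single edge addition improves a marginal-independence score, so
    greedy search from the empty graph is stuck at a local optimum while
    the global optimum links the parity triple.
    """
    rng = np.random.default_rng(11)
    n = 5000
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    c = (a ^ b) ^ (rng.random(n) < 0.1).astype(np.int64)
    d = rng.integers(0, 2, n)
    return binary_dataset({"A": a, "B": b, "C": c, "D": d})


@pytest.fixture(scope="session")
def vstructure_dataset():
    """Strong collider X -> Z <- Y with marginally visible dependence."""
    rng = np.random.default_rng(5)
    n = 20000
    x = rng.integers(0, 2, n)
    y = rng.integers(0, 2, n)
    pz = 0.9 * (x & y) + 0.6 * (x ^ y) + 0.05 * ((1 - x) & (1 - y))
    z = (rng.random(n) < pz).astype(np.int64)
    return binary_dataset({"X": x, "Y": y, "Z": z})


@pytest.fixture(scope="session")
def independent_dataset():
    rng = np.random.default_rng(9)
    n = 20000
    return binary_dataset({nm: rng.integers(0, 2, n) for nm in "PQR"})


@pytest.fixture(scope="session")
def core_population():
    """One shared draw of the 10-node ground-truth population."""
    from hcynet.synthetic import make_hhcy_population
    return make_hhcy_population(50000, 0)
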