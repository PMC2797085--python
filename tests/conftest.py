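import numpy as np
import pytest

from prince.netio import WeightedNetwork
from prince.synthetic import make_bundle


@pytest.fixture
def triangle():
    """Unit-weight triangle a-b-c."""
    return WeightedNetwork({("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0})


@pytest.fixture
def path_abc():
    """Unit-weight path a-b-c."""
    return WeightedNetwork({("a", "b"): 1.0, ("b", "c"): 1.0})


@pytest.fixture
def pair():
    """Single unit-weight edge a-b."""
    return WeightedNetwork({("a", "b"): 1.0})


@pytest.fixture(scope="session")
def small_bundle():
    """A downsized planted study for fast end-to-end tests."""
    return make_bundle(
        "easy",
        seed=11,
        n_proteins=300,
        n_modules=6,
        module_size=6,
        n_families=4,
        background_mean_degree=6.0,
    )


@pytest.fixture(scope="session")
def easy_bundle():
    """The full planted-recovery benchmark conditions."""
    return make_bundle("easy", seed=1)


@pytest.fixture(scope="session")
def null_bundle():
    """No phenotype signal, no coherent modules: calibration conditions."""
    return make_bundle("null", seed=3)


def random_network(rng: np.random.Generator, n: int = 40, p: float = 0.15) -> WeightedNetwork:
    """Random weighted graph guaranteed connected via a spanning chain."""
    edges = {}
    names = [f"n{i:03d}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(names[i], names[j])] = float(rng.uniform(0.05, 1.0))
    for i in range(n - 1):  # keep every node attached
        edges.setdefault((names[i], names[i + 1]), float(rng.uniform(0.05, 1.0)))
    return WeightedNetwork(edges)
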