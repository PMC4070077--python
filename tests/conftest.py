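import numpy as np
import pytest

from netprio.core import GeneSetCollection, GeneUniverse, WeightedNetwork
from netprio.synthfix import FixtureSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n=8, density=0.4, universe=None, name="rand"):
    """Small random symmetric nonnegative network for property tests."""
    if universe is None:
        universe = GeneUniverse(f"g{i}" for i in range(n))
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < density
    w[iu[mask], ju[mask]] = rng.uniform(0.1, 1.0, int(mask.sum()))
    w += w.T
    return WeightedNetwork(universe, w, name=name)


@pytest.fixture
def triangle_net():
    """Three genes a, b, c with edges a-b: 0.2, b-c: 0.5, a-c: 0.9."""
    universe = GeneUniverse(["a", "b", "c"])
    w = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.5], [0.9, 0.5, 0.0]])
    return WeightedNetwork(universe, w, name="triangle")


@pytest.fixture(scope="session")
def planted():
    """Small planted-structure benchmark shared by slower tests."""
    spec = FixtureSpec(n_genes=150, n_diseases=10, set_size=(5, 25), seed=42)
    col, sets, truth = generate(spec)
    return col, sets, truth


@pytest.fixture
def two_gene_sets():
    universe = GeneUniverse([f"g{i}" for i in range(10)])
    return GeneSetCollection(
        {"D1": ["g0", "g1", "g2"], "D2": ["g3", "g4", "g5", "g6"]}, universe
    )
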