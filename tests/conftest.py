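import numpy as np
import pytest

import coaldiv as cd
from coaldiv import simulate as sim


@pytest.fixture
def toy_tree():
    """3-tip caliper tree: node depths 2 and 1, terminal interval 1."""
    return cd.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_times(toy_tree):
    return cd.coalescent_times(toy_tree)


@pytest.fixture(scope="session")
def moran_tree():
    """One reconstructed Moran-model tree (N0=100, tau0=1), shared read-only."""
    return sim.simulate_saturated(100, 1.0, seed=101).tree


@pytest.fixture(scope="session")
def moran_times(moran_tree):
    return cd.coalescent_times(moran_tree)


@pytest.fixture(scope="session")
def yule_tree():
    """One 60-tip pure-birth tree, shared read-only."""
    return sim.simulate_yule(60, 1.0, seed=202).tree


@pytest.fixture(scope="session")
def yule_times(yule_tree):
    return cd.coalescent_times(yule_tree)


def random_times(rng: np.random.Generator, n: int, depth_scale: float = 1.0):
    """Arbitrary valid coalescent times (not from any model), for invariants."""
    depths = np.sort(rng.uniform(0.05, depth_scale, n - 1))[::-1]
    return cd.CoalescentTimes(n=n, node_depths=depths)
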