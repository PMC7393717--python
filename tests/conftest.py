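import dendropy
import numpy as np
import pytest

from modulevo import synthgen


def newick_tree(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """20-landmark, 10-OTU configuration used by fast end-to-end tests."""
    return synthgen.SimulationConfig(
        seed=1, n_otus=10, n_trees=5,
        module_sizes=(5, 5, 5, 5), rho_within=(0.7,) * 4, rho_between=0.2,
        curve_spec=(4, 4, 4, 4))


@pytest.fixture
def small_tree(small_config):
    return synthgen.simulate_tree(small_config)


@pytest.fixture
def small_dataset(small_config, small_tree):
    return synthgen.simulate_shapes(small_tree, small_config)
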