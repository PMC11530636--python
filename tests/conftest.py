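import numpy as np
import pytest

from aerodose.geometry import TreeSpec, cluster_spec, generate_airway_tree


@pytest.fixture(scope="session")
def mm_tree():
    """Five-generation tree at the mean-t_d / mean-b_a phenotype anchor."""
    return generate_airway_tree(cluster_spec("mm", n_generations=5, seed=4))


@pytest.fixture(scope="session")
def small_symmetric_tree():
    """Zero-asymmetry four-generation tree (exact left/right mirror)."""
    return generate_airway_tree(TreeSpec(t_d=16.0, b_a=80.0, n_generations=4, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
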