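from __future__ import annotations

import numpy as np
import pytest

from ampliphy.primer_design import PRIMER_PANEL
from ampliphy.simulate import SimConfig, generate_dataset, random_tree


@pytest.fixture(scope="session")
def panel():
    return PRIMER_PANEL


@pytest.fixture(scope="session")
def sim_truth():
    """A default 8-leaf synthetic marker-gene family with planted panel sites."""
    rng = np.random.default_rng(20240917)
    tree = random_tree(8, rng)
    return generate_dataset(SimConfig(tree=tree, seed=20240917))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
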