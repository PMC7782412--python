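import numpy as np
import pytest

import spikesim as ss
from spikesim.templategen import ForwardModelParams


@pytest.fixture(scope="session")
def tetrode():
    return ss.build_probe("tetrode")


@pytest.fixture(scope="session")
def cell_bank():
    return ss.default_cell_bank(seed=0)


@pytest.fixture(scope="session")
def small_library(cell_bank, tetrode):
    """Small non-drifting tetrode library shared across tests."""
    return ss.generate_templates(cell_bank, tetrode, n_per_model=6, seed=0)


@pytest.fixture(scope="session")
def drifting_library(cell_bank, tetrode):
    return ss.generate_templates(
        cell_bank, tetrode, n_per_model=2, drifting=True, n_drift_steps=30, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
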