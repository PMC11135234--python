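import numpy as np
import pytest

import uiknmf as u


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lowrank3():
    """Exact rank-3 positive 30x20 product (no noise)."""
    return u.make_lowrank_fixture(30, 20, 3, noise_sd=0.0, seed=42)


@pytest.fixture
def small_noisy():
    """Small noisy nonnegative matrix for generic fitting tests."""
    return u.make_lowrank_fixture(12, 9, 3, noise_sd=0.1, seed=3)


@pytest.fixture(scope="session")
def default_catalog():
    """One synthetic mutational catalog under the default study conditions."""
    return u.simulate_catalog(u.SimulationSpec(seed=0))
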