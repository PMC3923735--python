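import numpy as np
import pytest

import koehler


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_phantom():
    """One 128x128 phantom with the default planar field, shared read-only."""
    return koehler.generate_phantom(height=128, width=128, n_nuclei=10, seed=7)
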