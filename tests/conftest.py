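import numpy as np
import pytest

import fracspectral as fs


@pytest.fixture(scope="session")
def params():
    return fs.default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_states(rng):
    """Random biologically-scaled states (5, 100): cells up to ~1e7, E ~1e3."""
    scales = np.array([2.27e6, 2.27e7, 2.5e7, 3e5, 400.0])
    return rng.uniform(0.0, 1.5, size=(5, 100)) * scales[:, None]
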