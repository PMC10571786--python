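import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def random_rgb(rng):
    """Unit-range RGB image whose LMS values stay above the log floor."""
    return rng.uniform(0.05, 1.0, size=(24, 32, 3))
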