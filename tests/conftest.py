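import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_template(rng):
    """A generic 50x50 8-bit template with full-range noise."""
    return rng.integers(0, 256, size=(50, 50), dtype=np.uint8)
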