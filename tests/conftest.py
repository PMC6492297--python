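import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_dataset(rng):
    """Independent Y (30 x 8) and X (30 x 3): a global-null dataset."""
    y = rng.standard_normal((30, 8))
    x = rng.standard_normal((30, 3))
    return y, x
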