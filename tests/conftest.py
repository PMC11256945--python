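import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_view_instance(rng):
    """Small two-view, three-class instance with some class structure."""
    n = 18
    labels = np.repeat([0, 1, 2], 6)
    H1 = rng.standard_normal((n, 4))
    H2 = rng.standard_normal((n, 3))
    H1[labels == 1] += 1.2
    H2[labels == 2] -= 0.8
    return [H1, H2], labels
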