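import numpy as np
import pytest

from sfdepth import LayerStack, from_ratio


@pytest.fixture(scope="session")
def reference_props():
    """Homogeneous reference medium: mus'/mua = 100, l* = 1 mm, g = 0.8, n = 1.4."""
    return from_ratio(100.0, 1.0, g=0.8, n=1.4)


@pytest.fixture(scope="session")
def reference_stack(reference_props):
    return LayerStack.homogeneous(reference_props)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
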