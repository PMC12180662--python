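import numpy as np
import pytest

from sliceflow.backbones import TinyCNNAdapter
from sliceflow.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(16, 32, 32), n_normal=3, n_anomalous=2, seed=7)


@pytest.fixture(scope="session")
def tiny_backbone():
    return TinyCNNAdapter(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
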