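import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_gray(rng):
    def make(h=16, w=16):
        return rng.integers(0, 256, (h, w), dtype=np.uint8)

    return make


@pytest.fixture
def random_mask(rng):
    def make(h=16, w=16, p=0.5):
        return np.where(rng.random((h, w)) < p, 255, 0).astype(np.uint8)

    return make
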