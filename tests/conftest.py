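import numpy as np
import pytest

from emflowreg.stack_io import SectionStack
from emflowreg.synthetic import make_textured_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_image():
    return make_textured_image((96, 96), seed=11)


@pytest.fixture
def small_stack(rng):
    base = make_textured_image((64, 64), seed=3)
    secs = [np.clip(base + rng.normal(0, 0.01, base.shape), 0, 1) for _ in range(4)]
    return SectionStack(np.stack(secs))
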