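import numpy as np
import pytest

from dielcorrect import TimeGrid, preset_shape


@pytest.fixture
def grid():
    return TimeGrid(24)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unimodal():
    return preset_shape("unimodal")
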