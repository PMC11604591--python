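import numpy as np
import pytest

from saccade.model import ModelDims, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dims():
    return ModelDims(
        input_dim=6, glimpse_hidden=5, loc_hidden=4, g_dim=7, hidden=3, num_classes=3
    )


@pytest.fixture
def tiny_params(tiny_dims, rng):
    return init_params(tiny_dims, rng)
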