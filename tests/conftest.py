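import numpy as np
import pytest

from deeplight.model import build_model
from deeplight.synth import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """8x8 slices, two conv layers, 4-unit LSTMs, 3 states: fast and bias-free."""
    return build_model(
        (8, 8), n_states=3, hidden_size=4, conv_channels=(4, 4), conv_strides=(2, 1), seed=7
    )


@pytest.fixture
def small_synth_config():
    """Reduced-schedule generator config for fast unit tests (not the study defaults)."""
    return SyntheticConfig(
        grid_shape=(10, 10, 6),
        n_states=2,
        blocks_per_state=2,
        block_length=16.0,
        rest_length=8.0,
        roi_specs=[((3, 3, 3), 1.6), ((7, 7, 3), 1.6)],
        seed=11,
    )
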