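import numpy as np
import pytest

from iccode.model_core import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Minimal architecture for fast shape/gradient tests."""
    return ModelConfig(
        rate=2048.0, n_front_filters=3, front_kernel=9, encoder_layers=2,
        encoder_filters=4, encoder_kernel=6, bottleneck_filters=5, bottleneck_kernel=4,
        n_classes=5, frame=32, context=8, front_f_min=20.0,
    )


def tiny_cfg_variant(**overrides):
    base = dict(
        rate=2048.0, n_front_filters=3, front_kernel=9, encoder_layers=2,
        encoder_filters=4, encoder_kernel=6, bottleneck_filters=5, bottleneck_kernel=4,
        n_classes=5, frame=32, context=8, front_f_min=20.0,
    )
    base.update(overrides)
    return ModelConfig(**base)
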