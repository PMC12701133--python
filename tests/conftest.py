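import numpy as np
import pytest

from facesurv.config import DetectorConfig, EtedConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_detector_config():
    """Smallest detector that exercises every architectural component."""
    return DetectorConfig(
        image_size=64, stem_channels=4, body_widths=(6, 8, 10),
        body_depths=(1, 1, 1), pyramid_channels=6, head_channels=6,
        anchor_scales=(10.0, 20.0, 40.0), anchor_aspects=(0.35, 0.6, 1.0),
        steps=40, batch_size=4)


@pytest.fixture
def tiny_eted_config():
    return EtedConfig(hidden_size=8, n_timesteps=4, epochs=10, batch_size=16)
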