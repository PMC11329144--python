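import numpy as np
import pytest

from bruitnet.features import MelConfig
from bruitnet.model import ModelConfig
from bruitnet.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_config():
    """A miniature backbone for unit tests: full structure, minimal width."""
    return ModelConfig(
        block_channels=(2, 3, 4, 6, 8, 12),
        embed_dim=16,
        projection_dims=(8, 4),
    )


@pytest.fixture
def desk_mel_config():
    """16 frames/s at 4 kHz: a 20-s segment is 320x64, a 5-s crop 80x64."""
    return MelConfig(window_s=0.128, hop_s=0.0625)


@pytest.fixture
def short_synth_config():
    """Shortest valid recordings (just above the 20-s extraction minimum)."""
    return SynthConfig(duration=21.0, seed=7)
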