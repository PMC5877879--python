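import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from famorph import CalibratedImage, PipelineConfig, SceneParams, sample_scene


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def image(arr, px=1.0, channel=None):
    return CalibratedImage(np.asarray(arr, dtype=np.float64), px, channel)


@pytest.fixture
def small_scene():
    """5 well-separated cells with nuclei, low noise, 768x768."""
    params = SceneParams(image_shape=(768, 768), n_cells=5, noise_sd=0.01)
    return sample_scene(params, seed=42)
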