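import numpy as np
import pytest

from vesselseg.io import IHCImage
from vesselseg.synthesis import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def mid_entropy_scene():
    """One moderately complex scene shared by pipeline-level tests."""
    return generate_scene(SceneParams(target_entropy_bits=5.5, seed=101))


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config with a 4-frequency bank so 128-px test images fit."""
    from vesselseg.config import default_config

    cfg = default_config()
    cfg["gabor"]["n_freqs"] = 4
    return cfg


def make_image(arr, spacing=0.5) -> IHCImage:
    return IHCImage(np.asarray(arr, dtype=np.uint16), pixel_spacing_um=spacing)
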