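import numpy as np
import pytest

from stainseg import synthetic_data as sd
from stainseg.sie_encoder import EncoderConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg_64():
    """Tiny encoder preset on 64x64 inputs (CPU-friendly)."""
    return EncoderConfig.from_preset("tiny", input_size=64)


@pytest.fixture(scope="session")
def easy_spec():
    """Large, well-separated nuclei: the easiest segmentation setting."""
    return sd.NucleiSceneSpec(
        image_size=64, n_nuclei=3, radius_range=(7.0, 12.0),
        overlap_allowed=False, background_texture_scale=0.02,
    )


@pytest.fixture(scope="session")
def two_domains():
    return [
        sd.StainDomain(),
        sd.StainDomain(eosin_hue_shift=15.0, hematoxylin_hue_shift=-10.0, brightness_scale=1.1),
    ]


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory, easy_spec, two_domains):
    """Eight 64x64 synthetic images across two stain domains."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = sd.generate_corpus(8, easy_spec, two_domains, out, seed=11)
    return manifest
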