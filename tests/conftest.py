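import numpy as np
import pytest

from swirseg import PhantomConfig
from swirseg.pipeline import default_swir_rois


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def clean_reflectance():
    """Noise-free reflectance phantom with its standard ROIs."""
    cfg = PhantomConfig(noise_sigma=0.0, lesion_contrast_true=0.2)
    return cfg, default_swir_rois(cfg)
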