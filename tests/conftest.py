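import numpy as np
import pytest

from octpre import phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_phantoms():
    """Thirty 64x64 phantoms (mixed VMA/VMT) with ground truth."""
    return phantom.generate_samples(30, height=64, width=64, seed=101)


@pytest.fixture(scope="session")
def clean_vmt_sample():
    """One noiseless, fully visible VMT phantom at 128x128."""
    cfg = phantom.PhantomConfig.for_size(128, 128, seed=11, case_type="VMT",
                                         pcv_visibility=1.0, speckle_shape=None)
    img, mask, bounds = phantom.generate_phantom(cfg)
    return img, mask, bounds, cfg
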