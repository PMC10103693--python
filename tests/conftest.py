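import numpy as np
import pytest

from cvmbarrier.simulate import OpticsConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_optics():
    """Small fast field for rendering tests: 128x128 px, 2 s."""
    return OpticsConfig(image_shape=(128, 128), duration=2.0,
                        photon_scale=1000.0, background=50.0)


@pytest.fixture
def bimodal_log_msds():
    """1000 draws from 0.7 N(-2.5, 0.3^2) + 0.3 N(0, 0.3^2)."""
    r = np.random.default_rng(7)
    return np.concatenate([r.normal(-2.5, 0.3, 700), r.normal(0.0, 0.3, 300)])
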