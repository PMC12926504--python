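import numpy as np
import pytest

from fluordepth.models import make_channel
from fluordepth.optics import OpticalProperties


@pytest.fixture(scope="session")
def channel_pair():
    """The worked channel pair used across model tests.

    Target: mua=0.03, musp=1.0; reference: mua=0.05, musp=1.2; n=1.3.
    """
    target = make_channel("target", OpticalProperties(640.0, 0.03, 1.0, 1.3))
    reference = make_channel("reference", OpticalProperties(760.0, 0.05, 1.2, 1.3))
    return target, reference


@pytest.fixture(scope="session")
def prostate_spectra():
    from fluordepth.fixtures import prostate_like_spectra

    return prostate_like_spectra()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
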