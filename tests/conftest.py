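import numpy as np
import pytest

from qtsalvage import CmrPhantomParams, EcgSimParams, generate_cmr_phantom, generate_ecg
from qtsalvage.simulate import Sector


@pytest.fixture
def clean_ecg():
    """Noise-free default recording (QT 400 ms, RR 1 s) with ground truth."""
    return generate_ecg(EcgSimParams(qt_ms=400.0, rr_s=1.0, noise_sd_mv=0.0))


@pytest.fixture
def phantom_with_mvo():
    """Noise-free phantom carrying edema, infarct and an MVO core."""
    return generate_cmr_phantom(
        CmrPhantomParams(mvo_sector=Sector(0.0, 15.0), noise_sd=0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
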