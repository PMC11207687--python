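import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def biosemi_recording(rng):
    """A small random 64-channel recording with the BioSemi montage labels."""
    from vimsplv.recording import BIOSEMI64_LABELS, EEGRecording

    data = rng.normal(0.0, 10.0, (64, 2048))
    return EEGRecording(data, 2048.0, BIOSEMI64_LABELS)
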