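import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchsleep.containers import CHANNEL_LABELS, Recording

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(duration_s=60.0, fs=100.0, seed=0, n_channels=4, scale=30.0):
    """White-noise test recording with the canonical patch channel set."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    return Recording(
        samples=rng.normal(0.0, scale, size=(n_channels, n)),
        fs=fs,
        channel_labels=CHANNEL_LABELS[:n_channels],
    )


@pytest.fixture
def noise_recording():
    return make_recording()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
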