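import numpy as np
import pytest

from wakeripples.core import Recording
from wakeripples.simulate import SimConfig, one_over_f_noise


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator configuration: few channels, two short blocks."""
    return SimConfig(seed=7, n_blocks=2, trials_per_block=40,
                     n_channels_meg=6, n_channels_eeg=6)


def make_noise_recording(duration=60.0, fs=500.0, n_channels=1, seed=0,
                         modality="MEG"):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    data = np.stack([one_over_f_noise(n, 1.0, fs, rng)
                     for _ in range(n_channels)])
    labels = [f"ch{i}" for i in range(n_channels)]
    return Recording(data, fs, labels, [modality] * n_channels)


@pytest.fixture()
def noise_recording():
    return make_noise_recording()
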