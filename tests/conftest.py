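import numpy as np
import pytest

from cndspeech.audio import AudioToken
from cndspeech.periphery import PeripheryConfig, cf_grid


@pytest.fixture(scope="session")
def small_config():
    """Reduced CF grid / short windows for cheap periphery tests."""
    return PeripheryConfig(cf_list=cf_grid(5, 250.0, 4000.0))


@pytest.fixture(scope="session")
def default_config():
    return PeripheryConfig()


def tone_token(freq, dur=0.3, fs=100_000.0, fade=0.02, label="tone"):
    """Pure tone with raised-cosine fades (avoids broadband onset clicks)."""
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    n = int(fade * fs)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n)))
    x[:n] *= ramp
    x[-n:] *= ramp[::-1]
    return AudioToken(samples=x, fs=fs, label=label)


@pytest.fixture(scope="session")
def silence_1s():
    return AudioToken(samples=np.zeros(100_000), fs=100_000.0, label="silence")
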