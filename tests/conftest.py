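import numpy as np
import pytest

from neuroemotion import (
    RawRecording,
    ScenarioScript,
    default_profiles,
    generate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Two-channel recording: 10 Hz and 20 Hz unit tones at 1000 Hz."""
    fs = 1000.0
    t = np.arange(int(12 * fs)) / fs
    samples = np.stack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 20 * t)])
    return RawRecording(["CH1", "CH2"], fs, samples)


@pytest.fixture
def labeled_recording():
    """Synthetic 2-channel recording with one scripted emotion change."""
    script = ScenarioScript([("sad", 6.0), ("happy", 6.0)], n_channels=2, seed=11)
    return generate_recording(script, default_profiles())
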