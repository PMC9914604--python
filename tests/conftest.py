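import numpy as np
import pytest

from pulsebeat import SynthSpec, generate_video
from pulsebeat.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def short_video():
    """4-second 64 px pulsatile clip at 90 bpm — fast module-level fixture."""
    return generate_video(
        SynthSpec(bpm=90, fps=30, duration=4, frame_size=64, seed=11)
    )


@pytest.fixture(scope="session")
def short_spec():
    return SynthSpec(bpm=90, fps=30, duration=4, frame_size=64, seed=11)


@pytest.fixture()
def small_config():
    """Small preprocess target for fast tests."""
    return PreprocessConfig(target_size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
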