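import numpy as np
import pytest

from nightcough.audio_io import AudioSegment
from nightcough.features import FeatureConfig


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture()
def tone_segment():
    """One second of a 440 Hz tone at -6 dBFS."""
    sr = 22_050
    t = np.arange(sr) / sr
    return AudioSegment(0.5 * np.sin(2 * np.pi * 440.0 * t), sr)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small multi-participant event corpus for recognition unit tests."""
    from nightcough.synthetic import synth_event_corpus

    return synth_event_corpus(n_participants=8, coughs_per_participant=3,
                              noncoughs_per_participant=6, seed=7)


@pytest.fixture(scope="session")
def tiny_windows(tiny_corpus):
    from nightcough.recognition import windows_from_corpus

    return windows_from_corpus(tiny_corpus)
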