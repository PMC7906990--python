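import numpy as np
import pytest

from vretsim import EdaTrace, ParticipantProfile, SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_trace():
    """120 s of constant raw EDA 5.0 at 100 Hz."""
    return EdaTrace.from_values(np.full(12_000, 5.0))


@pytest.fixture
def median_profile():
    return ParticipantProfile(sensitivity=1.0, latency=3.0, seed=7)


@pytest.fixture
def session_config():
    return SessionConfig(seed=3)
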