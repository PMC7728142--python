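import numpy as np
import pytest

from musemi import (
    BandPowerRecording,
    SessionConfig,
    SyntheticConfig,
    generate_continuous_session,
    generate_trial,
)


@pytest.fixture
def synth_cfg():
    return SyntheticConfig()


@pytest.fixture
def short_cfg():
    """A 6 s trial config to keep per-test generation light."""
    return SyntheticConfig(trial_duration=6.0)


@pytest.fixture
def clean_trial(short_cfg):
    return generate_trial(short_cfg, "left", seed=1)


@pytest.fixture
def continuous_session(synth_cfg):
    return generate_continuous_session(synth_cfg, seed=1, participant_id="P1")


@pytest.fixture
def ramp_recording():
    """A deterministic recording whose signals are linear ramps."""
    n = 1024
    ts = np.arange(n) / 256.0
    base = np.arange(n, dtype=float)[:, None]
    values = base + np.arange(20)[None, :] * 0.1
    return BandPowerRecording(timestamps=ts, values=values, label="left",
                              recording_id="ramp")


@pytest.fixture
def default_session_cfg():
    return SessionConfig()
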