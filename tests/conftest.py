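import numpy as np
import pytest

from phasestim import (
    EEGRecording,
    SynthConfig,
    TrackerConfig,
    generate_pure_alpha,
    generate_session_with_truth,
)

FS = 1000.0


@pytest.fixture(scope="session")
def small_session():
    """A compact jittered-alpha session shared by read-only tests."""
    cfg = SynthConfig(n_trials=8, n_channels=6, seed=42)
    rec, truth = generate_session_with_truth(cfg)
    return cfg, rec, truth


@pytest.fixture()
def pure_sine_recording():
    """Noiseless 10 Hz recording (phase known in closed form)."""
    x = generate_pure_alpha(10.0, FS, 10.0, 0.0)
    return EEGRecording(
        data=np.vstack([x, x]), fs=FS, channel_labels=["C4", "C3"]
    )


@pytest.fixture(scope="session")
def tracker_cfg():
    return TrackerConfig(fs=FS)
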