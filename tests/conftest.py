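import numpy as np
import pytest

from eegskill.cohort import CohortConfig, generate_recording
from eegskill.recording import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A short, cheap cohort configuration for unit tests."""
    return CohortConfig(n_subjects=6, duration_s=20.0, seed=7)


@pytest.fixture
def sim_recording(small_cfg):
    """One 56 s synthetic recording (36 s baseline + 20 s task)."""
    return generate_recording("moderate", small_cfg, seed=11)


@pytest.fixture
def noise_recording(rng):
    """A 4-channel white-noise recording with a 5 s baseline, no generator frills."""
    fs = 128.0
    n = int(25 * fs)
    data = rng.normal(0.0, 10.0, size=(4, n))
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=("AF3", "AF4", "F3", "F4"),
        baseline_span=(0, int(5 * fs)),
        subject_id="noise",
    )
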