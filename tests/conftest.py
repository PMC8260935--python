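import numpy as np
import pytest

from nervedecode import features, preprocessing, synth
from nervedecode.gestures import codebook, lookup


@pytest.fixture(scope="session")
def small_session():
    """Two-gesture session (thumb + rest), 3 reps each, noiseless-ish."""
    cfg = synth.SessionConfig(n_repetitions=3, snr_db=30.0, rng_seed=42)
    recording, traj = synth.generate_session(cfg, [lookup("thumb"), lookup("rest")])
    return cfg, recording, traj


@pytest.fixture(scope="session")
def small_trials(small_session):
    _, recording, traj = small_session
    return preprocessing.cut_trials(recording, traj)


@pytest.fixture(scope="session")
def small_grid(small_session):
    _, recording, _ = small_session
    return features.extract_grid(recording.samples, recording.sample_rate)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
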