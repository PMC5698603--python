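import numpy as np
import pytest

import p300grid as pg


@pytest.fixture(scope="session")
def layout():
    return pg.load_layout()


@pytest.fixture(scope="session")
def small_recording():
    """Two short sessions — enough structure to exercise every stage cheaply."""
    specs = pg.subject_session_specs(n_sessions=2, n_trials=60, seed=0)
    return pg.synthesize_recording(specs, p300=pg.P300Params(amplitude=10.0), seed=0)


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    return pg.epoch_trials(small_recording)


@pytest.fixture(scope="session")
def subject_recording():
    """One full simulated subject: 12 sessions x 180 trials, 500 ms, 10 uV P300."""
    specs = pg.subject_session_specs(trial_length_ms=500.0, seed=0)
    return pg.synthesize_recording(specs, p300=pg.P300Params(amplitude=10.0), seed=0)


@pytest.fixture(scope="session")
def subject_epochs(subject_recording):
    return pg.epoch_trials(subject_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
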