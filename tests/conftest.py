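import numpy as np
import pytest

from midecode import spectrogram, synthetic


@pytest.fixture(scope="session")
def small_session():
    """One deterministic 2-run synthetic session (96 trials)."""
    profile = synthetic.SubjectProfile(rng_seed=7)
    schedule = synthetic.SessionSchedule(n_runs=2)
    return synthetic.generate_session(profile, schedule, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_images(small_session):
    return spectrogram.images_for_trialset(small_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
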