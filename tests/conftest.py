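import numpy as np
import pandas as pd
import pytest

import lateraldopa as ld


@pytest.fixture(scope="session")
def task():
    return ld.TaskConfig()


@pytest.fixture(scope="session")
def observer():
    return ld.ObserverParams()


@pytest.fixture(scope="session")
def trials_small(task, observer):
    return ld.generate_trials(task, observer, 200, seed=11)


@pytest.fixture(scope="session")
def vs_session(task, observer):
    """Low-noise, artifact-free VS session for recovery checks."""
    photo = ld.PhotometryConfig(profile="VS", noise_sd=0.001, artifact_rate=0.0)
    return ld.generate_session(task, observer, photo, 150, seed=21)


@pytest.fixture(scope="session")
def dms_session(task, observer):
    photo = ld.PhotometryConfig(profile="DMS", hemisphere="L", noise_sd=0.001, artifact_rate=0.0)
    return ld.generate_session(task, observer, photo, 300, seed=22, pupil_coupling=0.0)


@pytest.fixture()
def flat_amplitudes():
    def make(trials):
        return pd.DataFrame(
            {"stimulus": 0.0, "action": 0.0, "outcome": 0.0}, index=trials.index
        )

    return make
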