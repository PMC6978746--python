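import numpy as np
import pandas as pd
import pytest

import fsrgesture as fg
from fsrgesture.features import feature_columns


@pytest.fixture(scope="session")
def profile():
    return fg.default_activation_profile()


@pytest.fixture(scope="session")
def acq():
    return fg.AcquisitionConfig()


@pytest.fixture(scope="session")
def fist_trial(profile):
    """Ten consecutive clenched-fist repetitions (seed 1)."""
    return fg.generate_trial(profile, 10, [fg.GestureLabel.CLENCHED_FIST], seed=1)


@pytest.fixture(scope="session")
def session0(profile):
    """Full protocol session of one default-variability subject."""
    rng = np.random.default_rng(0)
    prof = fg.subject_profile(profile, rng)
    return fg.simulate_session(prof, 10, seed=rng, subject_id="S00")


@pytest.fixture(scope="session")
def db0(session0):
    return fg.session_database(session0)


@pytest.fixture(scope="session")
def cohort_dbs(profile):
    """Ten default synthetic subjects (seeds 0..9), batch pipeline applied."""
    dbs = []
    for i in range(10):
        rng = np.random.default_rng(i)
        prof = fg.subject_profile(profile, rng)
        sess = fg.simulate_session(prof, 10, seed=rng, subject_id=f"S{i:02d}")
        dbs.append(fg.session_database(sess))
    return dbs


def make_feature_database(
    seed: int,
    n_classes: int = 8,
    rows_per_class: int = 10,
    spread: float = 0.6,
    noise: float = 0.12,
) -> fg.GestureDatabase:
    """Random Gaussian-cluster feature database (moderate class overlap),
    used to exercise the classifiers away from the generator's
    perfectly-separated regime."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c in range(n_classes):
        center = rng.uniform(0.0, spread, size=6)
        rows.append(center + rng.normal(0.0, noise, size=(rows_per_class, 6)))
        labels += [c] * rows_per_class
    frame = pd.DataFrame(np.vstack(rows), columns=feature_columns())
    frame["label"] = labels
    return fg.GestureDatabase(frame, subject_id=f"synthetic{seed}")
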