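import numpy as np
import pytest

from blinkkin import SubjectProfile, make_feature_dataset, make_segment


@pytest.fixture(scope="session")
def default_profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def noiseless_blink(default_profile):
    """One clean default blink segment with its dense-grid ground truth."""
    return make_segment(default_profile, noise_sd=0.0, with_truth=True)


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic study geometry: 26 subjects x 74 trials of pipeline features.

    Session-scoped because generation runs the full feature pipeline on 1924
    noisy blink windows.
    """
    ds, profiles = make_feature_dataset(n_subjects=26, trials=74, seed=1)
    return ds, profiles


@pytest.fixture(scope="session")
def small_dataset():
    """A faster 8-subject x 20-trial dataset for unit-level checks."""
    ds, profiles = make_feature_dataset(n_subjects=8, trials=20, seed=3)
    return ds, profiles
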