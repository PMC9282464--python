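import numpy as np
import pytest

from ecochg import CohortConfig, build_labelled_series, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noiseless-ish cohort shared by classifier/CLI tests."""
    cfg = CohortConfig(
        n_patients=8,
        n_timepoints=40,
        drop_prob=0.5,
        noise_sd=0.05,
        baseline_cm_range=(3.0, 20.0),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_series(tiny_cohort):
    return [
        build_labelled_series(rec, tiny_cohort.annotations[rec.patient_id])
        for rec in tiny_cohort.recordings
    ]
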