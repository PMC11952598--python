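from datetime import date

import pytest

from fireits.studies import study_config, study_cv, study_learner_spec
from fireits.synthetic import generate_covariates, generate_visits


@pytest.fixture(scope="session")
def lifted_config():
    """Single-cell design with a 41% lift on post-event days 0-6."""
    return study_config(lift=1.41)


@pytest.fixture(scope="session")
def null_config():
    return study_config(lift=1.0)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    covariates = generate_covariates(null_config, seed=11)
    visits, truth = generate_visits(null_config, covariates, seed=12)
    return covariates, visits, truth


@pytest.fixture(scope="session")
def fast_spec():
    return study_learner_spec()


@pytest.fixture(scope="session")
def fast_cv():
    return study_cv()


@pytest.fixture(scope="session")
def single_window_config():
    """One 2024-06-01..2024-12-17 window (200 days), event 2024-11-01."""
    return study_config(lift=1.0, dispersion=50.0).replace(
        seasonal_windows=((date(2024, 6, 1), date(2024, 12, 17)),),
        event_date=date(2024, 11, 1),
    )
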