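import pytest

from curb65a.cohort import CohortConfig, generate_cohort_frame
from curb65a.evaluation import prepare_frame


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n=5000, seed=20)


@pytest.fixture(scope="session")
def cohort_frame(default_config):
    """A mid-size synthetic cohort shared across evaluation tests."""
    return generate_cohort_frame(default_config)


@pytest.fixture(scope="session")
def scored_frame(cohort_frame):
    return prepare_frame(cohort_frame)
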