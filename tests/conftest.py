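import numpy as np
import pytest

from tsst_resilience.cohort import CohortConfig, generate_cohort
from tsst_resilience.composite import compute_composites
from tsst_resilience.features import compute_features


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort for fast unit tests."""
    return generate_cohort(CohortConfig(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return compute_features(small_cohort.physio)


@pytest.fixture(scope="session")
def small_composites(small_features):
    composites, report = compute_composites(small_features)
    return composites, report


@pytest.fixture(scope="session")
def full_cohort():
    """A full-size cohort at the study's sample size."""
    return generate_cohort(CohortConfig(n_participants=248, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
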