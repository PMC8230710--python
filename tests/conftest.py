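import numpy as np
import pytest

from arsenspec.preprocess import assign_quartiles, build_profiles, filter_by_creatinine
from arsenspec.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def cohort457():
    """Default-condition cohort at the study's sample size."""
    return generate_cohort(CohortParams(n_subjects=457, seed=1))


@pytest.fixture(scope="session")
def profiles457(cohort457):
    kept, _ = filter_by_creatinine(cohort457)
    return assign_quartiles(build_profiles(kept))


@pytest.fixture(scope="session")
def cohort5000():
    """Larger cohort for Monte-Carlo checks of generator moments."""
    return generate_cohort(CohortParams(n_subjects=5000, seed=1))


@pytest.fixture(scope="session")
def profiles5000(cohort5000):
    kept, _ = filter_by_creatinine(cohort5000)
    return assign_quartiles(build_profiles(kept))


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)
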