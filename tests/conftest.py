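import numpy as np
import pytest

from karyocohort import CohortConfig, classify_cohort, cohort_to_dataframe, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-sample default-configured synthetic cohort (fixed seed)."""
    return generate_cohort(CohortConfig(n_samples=4_000, seed=7))


@pytest.fixture(scope="session")
def small_classified(small_cohort):
    """The same cohort as a classified DataFrame (failed samples dropped)."""
    return classify_cohort(cohort_to_dataframe(small_cohort))
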