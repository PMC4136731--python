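import numpy as np
import pytest
from hypothesis import settings

from gcc2vfs.cohort import CohortConfig, generate_cohort
from gcc2vfs.geometry import build_hfa10_2_grid

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return build_hfa10_2_grid()


@pytest.fixture(scope="session")
def synthetic_table():
    """Default-condition synthetic cohort (83 eyes, study covariates)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def large_synthetic_table():
    """A larger cohort for low-noise refit checks."""
    return generate_cohort(CohortConfig(n_eyes=400, seed=11))
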