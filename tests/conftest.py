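import numpy as np
import pytest

from ezh2screen import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240205)
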