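import numpy as np
import pytest

from epifounder import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-design cohort (45/56 individuals, founders 8/10, seed 7)."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
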