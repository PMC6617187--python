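import numpy as np
import pytest

from pcatriage.synthetic import (
    CohortConfig,
    generate_biopsy_cohort,
    generate_life_table,
    generate_life_table_cohort,
    generate_survival_cohort,
)


@pytest.fixture(scope="session")
def biopsy_cohort():
    """Default-size screening biopsy cohort, fixed seed."""
    return generate_biopsy_cohort(CohortConfig(n=3616, seed=1))


@pytest.fixture(scope="session")
def small_biopsy_cohort():
    """A smaller cohort for bootstrap-heavy tests."""
    return generate_biopsy_cohort(CohortConfig(n=800, seed=7))


@pytest.fixture(scope="session")
def survival_cohort():
    """Full-size no-csPCa follow-up cohort, fixed seed."""
    return generate_survival_cohort(n=19000, seed=2)


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def life_table_cohort(life_table):
    """Cohort simulated at life-table/1.6 (healthy-screenee structure)."""
    return generate_life_table_cohort(19000, 3, life_table, hazard_ratio=1.6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
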