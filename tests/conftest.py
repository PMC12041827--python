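import numpy as np
import pytest

from lpakit import cohort


@pytest.fixture(scope="session")
def default_cfg():
    return cohort.default_config()


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient cohort from the calibrated generator (fast fixture)."""
    cfg = cohort.default_config(n_patients=600)
    return cohort.generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def full_cohort():
    """One full-size calibrated cohort (n=3941)."""
    return cohort.generate_cohort(cohort.default_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def order_by_teams():
    return [cohort.INDICATORS.index(c) for c in cohort.TEAM_INDICATORS]
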