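import numpy as np
import pytest

import lesiontrack as lt
from lesiontrack.models import CohortData


@pytest.fixture(scope="session")
def desk():
    return lt.desk_profile()


@pytest.fixture(scope="session")
def noiseless_spec():
    return lt.CohortSpec(n_cases=8, noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def pd_case(noiseless_spec):
    return lt.generate_case(
        noiseless_spec, lt.PD, seed=7, schedule_mm=[20, 10, 8, 14]
    )


@pytest.fixture(scope="session")
def shrinking_case(noiseless_spec):
    return lt.generate_case(
        noiseless_spec, lt.NON_PD, seed=9, schedule_mm=[20, 10, 6, 4]
    )


@pytest.fixture(scope="session")
def tiny_cohort(desk):
    """24-case desk cohort, preprocessed once per session."""
    spec = lt.CohortSpec(n_cases=24, seed=2)
    return CohortData.from_spec(spec, desk)


@pytest.fixture(scope="session")
def micro_train_config(desk):
    """Short training runs for smoke tests."""
    from lesiontrack.config import scaled

    return scaled(desk, epochs=2).train


@pytest.fixture
def rng():
    return np.random.default_rng(123)
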