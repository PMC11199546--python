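import numpy as np
import pytest

from fetalflux.types import CalibrationModel, CohortConfig
from fetalflux.synthetic import make_cohort


@pytest.fixture
def calib() -> CalibrationModel:
    return CalibrationModel()


@pytest.fixture(scope="session")
def default_cohort():
    """One 12-vs-9 cohort generated with the default design, seed 0."""
    return make_cohort(CohortConfig(seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
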