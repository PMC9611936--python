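import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from busudose import (
    IndividualParameters,
    NonparametricModelSpec,
    ParametricModelSpec,
    PatientCovariates,
    Regimen,
)


@pytest.fixture(scope="session")
def par_spec() -> ParametricModelSpec:
    return ParametricModelSpec()


@pytest.fixture(scope="session")
def np_spec() -> NonparametricModelSpec:
    return NonparametricModelSpec()


@pytest.fixture
def reference_params() -> IndividualParameters:
    """CL at the typical 9-kg value, a plausible infant volume."""
    return IndividualParameters(clearance=2.18, volume=6.62)


@pytest.fixture
def single_dose() -> Regimen:
    return Regimen.uniform(dose=10.9, n_doses=1, interval=6.0, duration=2.0)


@pytest.fixture
def full_course() -> Regimen:
    return Regimen.uniform(dose=10.9, n_doses=16, interval=6.0, duration=2.0)


@pytest.fixture
def median_child() -> PatientCovariates:
    return PatientCovariates(body_weight=16.7, height=103.0, age=4.0, sex="female")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
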