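import numpy as np
import pytest

from bpoplan import (
    CohortSpec,
    PatientSpec,
    default_fixture_fulcrum,
    default_muscle_fixture,
    make_patient,
    sample_patient_specs,
)

#: Baseline of the packaged example-patient linear models: SVA 223.8 mm,
#: PI 54.4°, PT 10.4°, TPA 27.0°; LL chosen so PI − LL starts at 28.2°.
EXAMPLE_LL_DEG = 26.2


@pytest.fixture(scope="session")
def deformity_spec() -> PatientSpec:
    """A severe rigid sagittal deformity resembling the example patient."""
    return PatientSpec(pi_deg=54.4, pt_deg=25.0, sva_mm=224.0, ll_deg=EXAMPLE_LL_DEG)


@pytest.fixture(scope="session")
def deformity_landmarks(deformity_spec):
    return make_patient(deformity_spec)


@pytest.fixture(scope="session")
def cohort_specs():
    """Twenty plausible deformity patients, fixed seed."""
    return sample_patient_specs(CohortSpec(n=20, seed=20240117))


@pytest.fixture(scope="session")
def oa_grid():
    return np.arange(0.0, 41.0, 1.0)


@pytest.fixture(scope="session")
def muscle_fixture():
    return default_muscle_fixture()


@pytest.fixture(scope="session")
def fixture_fulcrum():
    return default_fixture_fulcrum()
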