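import numpy as np
import pytest

from aegfr.cohort import CohortSpec, generate_cohort
from aegfr.records import PatientRecord


@pytest.fixture
def median_patient():
    """A subject at the study population's median covariates."""
    return PatientRecord(
        id="median", sex="female", age=50.0, weight=91.0, height=165.0,
        diabetes=False, hypertension=False, single_kidney=False,
        scr=0.85, urea=31.1, albumin=4.2, mgfr_indexed=91.2,
    )


@pytest.fixture(scope="session")
def forward_cohort():
    """Small forward-mode synthetic cohort with measured GFR."""
    return generate_cohort(CohortSpec(n=400, seed=20230401))


@pytest.fixture
def rng():
    return np.random.default_rng(915)
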