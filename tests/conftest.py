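import numpy as np
import pytest

from relapsim.cohort import CohortConfig, generate_cohort
from relapsim.degrade import DegradeConfig, make_variants
from relapsim.disease_models import AMLParameters, CMLParameters, TreatmentSchedule
from relapsim import priors


@pytest.fixture(scope="session")
def aml_params():
    return priors.default_aml_parameters(*priors.AML_BASE[0])


@pytest.fixture(scope="session")
def cml_params():
    return priors.default_cml_parameters(
        **dict(zip(priors.CML_FREE, priors.CML_BASE[0])))


@pytest.fixture(scope="session")
def aml_schedule():
    starts = np.array([0.0, 35.0, 70.0, 105.0])
    return TreatmentSchedule(disease="AML",
                             cycles=tuple((s, s + 7.0) for s in starts))


@pytest.fixture(scope="session")
def cml_schedule():
    return TreatmentSchedule(disease="CML", t_stop=92.0)


@pytest.fixture(scope="session")
def aml_cohort():
    return generate_cohort(CohortConfig("AML", 60, seed=101))


@pytest.fixture(scope="session")
def cml_cohort():
    return generate_cohort(CohortConfig("CML", 40, seed=101))


@pytest.fixture(scope="session")
def aml_variants(aml_cohort):
    return make_variants(aml_cohort, DegradeConfig("AML", seed=7),
                         variants=("D", "DN", "SN", "AP", "AS"))


@pytest.fixture(scope="session")
def cml_variants(cml_cohort):
    return make_variants(cml_cohort, DegradeConfig("CML", seed=7),
                         variants=("D", "DN", "SN", "AP", "AS"))
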