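import pytest

import daptopk as dp


@pytest.fixture(scope="session")
def drug():
    return dp.DrugParameters.default()


@pytest.fixture(scope="session")
def adult_subject():
    """The healthy 70-kg reference adult (35 y, BMI 25.71)."""
    return dp.make_subject(35, 70, 25.71, dp.RenalFunctionCategory.HEALTHY, dp.Population.ADULT)


@pytest.fixture(scope="session")
def adult_model(adult_subject):
    """Clearance model anchored to the 6 mg/kg day-5 reference AUC (420 mg / 580 ug.h/mL)."""
    return dp.build_clearance_model(adult_subject, dp.cl_from_dose_auc(420.0, 580.0))


@pytest.fixture(scope="session")
def calibrated(adult_subject, drug):
    """Full disposition calibration against the adult reference AUC and Cmax."""
    return dp.calibrate_adult_disposition(adult_subject, drug)


@pytest.fixture(scope="session")
def pediatric_models():
    return dp.PediatricModels.default()
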