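import numpy as np
import pytest

import riskpath as rp
from riskpath.synthdata import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def bundle():
    return rp.default_bundle()


@pytest.fixture()
def example_state():
    """A typical pooled-trial participant: white female, 64 y at
    randomisation, 16 years of diabetes."""
    vals = {"hdl": 1.1, "ldl": 2.2, "sbp": 135.0, "hba1c": 7.0,
            "haemoglobin": 13.8, "heart_rate": 72.0, "bmi": 30.0}
    return rp.PatientState(
        id="pt-1", age_at_rand=64.0, female=True, ethnicity="white",
        smoker_baseline=False, duration=16.0, current=dict(vals),
        first_recorded=dict(vals), egfr=75.0, egfr_first=75.0)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_patients=300, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
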