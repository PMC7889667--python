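import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cci_lt.cci_core import ClavienDindoGrade, ComplicationEvent
from cci_lt.synthetic_cohort import generate_cohort, preset


def make_events(grades, patient_id="p1", **kwargs):
    """Build a one-patient course from grade labels like ["I", "IIIb"]."""
    return [
        ComplicationEvent(patient_id, ClavienDindoGrade[g], **kwargs) for g in grades
    ]


@pytest.fixture(scope="session")
def training_cohort():
    """One fixed moderate-size training-like cohort shared across tests."""
    return generate_cohort(preset("training_like", n_patients=1500), seed=20240)


@pytest.fixture
def rng():
    return np.random.default_rng(991)
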