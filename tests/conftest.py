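import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frailvig import load_fixture
from frailvig.instrument import (
    BINARY_ITEMS,
    DISEASE_ITEMS,
    AssessmentRecord,
    CognitiveLevel,
    DepressiveStatus,
    DiseaseStatus,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(patient_id="p0", **overrides) -> AssessmentRecord:
    """A fully answered record with no deficits, overridable per item."""
    base = dict(
        patient_id=patient_id,
        barthel=100,
        cognitive=CognitiveLevel.NONE,
        depressive=DepressiveStatus.NO,
        **{item: False for item in BINARY_ITEMS},
        **{item: DiseaseStatus.ABSENT for item in DISEASE_ITEMS},
    )
    base.update(overrides)
    return AssessmentRecord(**base)


def random_record(rng: np.random.Generator, patient_id="r", allow_advanced=True):
    disease_levels = [DiseaseStatus.ABSENT, DiseaseStatus.PRESENT]
    if allow_advanced:
        disease_levels.append(DiseaseStatus.ADVANCED)
    return make_record(
        patient_id=patient_id,
        barthel=int(rng.integers(0, 21)) * 5,
        cognitive=list(CognitiveLevel)[rng.integers(3)],
        depressive=[DepressiveStatus.NO, DepressiveStatus.YES][rng.integers(2)],
        **{item: bool(rng.integers(2)) for item in BINARY_ITEMS},
        **{item: disease_levels[rng.integers(len(disease_levels))] for item in DISEASE_ITEMS},
    )


@pytest.fixture(scope="session")
def table3_12m():
    return load_fixture("table3_12m")


@pytest.fixture(scope="session")
def table3_24m():
    return load_fixture("table3_24m")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_prevalence")


@pytest.fixture
def worked_record():
    """Seven-point example: IADL money + moderate dependency + mild cognitive
    impairment + polypharmacy + dysphagia + cardiac disease present."""
    return make_record(
        patient_id="worked",
        iadl_money=True,
        barthel=45,
        cognitive=CognitiveLevel.MILD_MODERATE,
        polypharmacy=True,
        dysphagia=True,
        disease_cardiac=DiseaseStatus.PRESENT,
    )
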