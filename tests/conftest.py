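import pytest

from sarcoscreen import (
    Anthropometry,
    CohortSpec,
    Difficulty,
    Patient,
    SarcFResponse,
    Sex,
)


@pytest.fixture
def male_70() -> Patient:
    """The worked-example patient: 70-year-old white/Hispanic man, 1.70 m."""
    return Patient(patient_id="P-001", sex=Sex.male, age=70, height=1.70)


@pytest.fixture
def worked_anthropometry() -> Anthropometry:
    """Measurements whose corrected girths are 26.8584 / 44.2301 / 32.4867 cm.

    arm 30 cm − π·1.0 cm, thigh 47.372 cm − π·1.0 cm, calf 35 cm − π·0.8 cm.
    """
    return Anthropometry(
        arm_circ=30.0,
        thigh_circ=47.371693,
        calf_circ=35.0,
        biceps_skf=6.0,
        triceps_skf=10.0,
        thigh_skf=10.0,
        calf_skf=8.0,
    )


@pytest.fixture
def worst_response() -> SarcFResponse:
    return SarcFResponse(
        strength_difficulty=Difficulty.worst,
        walking_difficulty=Difficulty.worst,
        chair_transfer_difficulty=Difficulty.worst,
        stair_difficulty=Difficulty.worst,
        falls_last_year=6,
    )


@pytest.fixture
def mixed_spec() -> CohortSpec:
    """The canonical 100-patient cohort: 50 healthy / 30 probable /
    15 confirmed / 5 severe, seed 42."""
    return CohortSpec(
        n=100,
        seed=42,
        proportions={"healthy": 0.5, "probable": 0.3, "confirmed": 0.15, "severe": 0.05},
    )
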