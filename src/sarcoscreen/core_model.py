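"""Shared domain types and the FACS grading state machine.

The engine follows the EWGSOP2 Find-Assess-Confirm-Severity (FACS)
workflow.  Each measurement stage reduces to a three-valued verdict
(:class:`StageVerdict`): ``low``, ``not_low``, or ``unknown`` when the
stage was not administered.  The final grade is a pure function of the
three stage verdicts:

* low muscle *strength* is the diagnosis criterion — without it there is
  no sarcopenia grade beyond ``no_sarcopenia``;
* low muscle *quantity* confirms the diagnosis;
* low physical *performance* marks the confirmed case as severe.

The SARC-F case-finding score is recorded alongside but never gates the
grade: a negative screen does not block assessment and a positive screen
does not create a diagnosis.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .config import Cutoffs, DEFAULT_CUTOFFS


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Ethnicity(str, enum.Enum):
    """Ethnicity groups of the anthropometric muscle-mass model's race term."""

    white_hispanic = "white_hispanic"
    black = "black"
    asian = "asian"


class StageVerdict(str, enum.Enum):
    low = "low"
    not_low = "not_low"
    unknown = "unknown"


class Grade(str, enum.Enum):
    not_assessed = "not_assessed"
    no_sarcopenia = "no_sarcopenia"
    probable_sarcopenia = "probable_sarcopenia"
    confirmed_sarcopenia = "confirmed_sarcopenia"
    severe_sarcopenia = "severe_sarcopenia"


#: Strict severity order among the assessed grades (not_assessed is not
#: comparable and is deliberately absent).
GRADE_SEVERITY: dict[Grade, int] = {
    Grade.no_sarcopenia: 0,
    Grade.probable_sarcopenia: 1,
    Grade.confirmed_sarcopenia: 2,
    Grade.severe_sarcopenia: 3,
}


class Patient(BaseModel):
    """Demographics needed by the sex/age/ethnicity-specific rules."""

    model_config = ConfigDict(frozen=True)

    patient_id: str = Field(min_length=1)
    sex: Sex
    age: int = Field(ge=18, description="age in completed years")
    height: float = Field(gt=0.5, lt=2.5, description="standing height in meters")
    ethnicity: Ethnicity = Ethnicity.white_hispanic
    name: Optional[str] = None
    birthdate: Optional[str] = None


class SarcopeniaAssessment(BaseModel):
    """Per-stage verdicts plus the final FACS grade for one patient."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    sarcf_total: Optional[int] = Field(default=None, ge=0, le=10)
    sarcf_positive: Optional[bool] = None
    strength: StageVerdict
    quantity: StageVerdict
    performance: StageVerdict
    grade: Grade
    incomplete_flags: tuple[str, ...] = ()
    # measured values carried along for reporting; None when not administered
    grip_best_kg: Optional[float] = None
    sts_best_s: Optional[float] = None
    sm_kg: Optional[float] = None
    smi_kg_m2: Optional[float] = None
    gait_speed_m_s: Optional[float] = None


def classify(
    strength: StageVerdict,
    quantity: StageVerdict,
    performance: StageVerdict,
) -> Grade:
    """Combine the three stage verdicts into the final grade.

    Decision table (total over all 27 verdict combinations):

    ==========  ==========  ===========  =====================
    strength    quantity    performance  grade
    ==========  ==========  ===========  =====================
    unknown     any         any          not_assessed
    not_low     any         any          no_sarcopenia
    low         not low*    any          probable_sarcopenia
    low         low         not low*     confirmed_sarcopenia
    low         low         low          severe_sarcopenia
    ==========  ==========  ===========  =====================

    where *not low* covers both ``not_low`` and ``unknown``: a grade of
    confirmed or severe must rest on a measured low flag, never on the
    absence of a measurement.
    """
    if strength is StageVerdict.unknown:
        return Grade.not_assessed
    if strength is StageVerdict.not_low:
        return Grade.no_sarcopenia
    if quantity is not StageVerdict.low:
        return Grade.probable_sarcopenia
    if performance is not StageVerdict.low:
        return Grade.confirmed_sarcopenia
    return Grade.severe_sarcopenia


def assemble_assessment(
    patient: Patient,
    sarcf=None,
    grip=None,
    sts=None,
    anthropometry=None,
    gait=None,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> SarcopeniaAssessment:
    """Run every administered stage and grade the patient.

    Any subset of stage inputs may be ``None`` (stage not administered);
    absent stages map to ``unknown`` verdicts and are listed in
    ``incomplete_flags``.  ``sarcf`` may be a raw :class:`~sarcoscreen.sarcf.
    SarcFResponse` or an already-computed score; it is recorded but never
    influences the grade.
    """
    # stage modules import this module's types; import them lazily here to
    # keep the dependency graph acyclic
    from . import body_composition as _bc
    from . import performance as _perf
    from . import sarcf as _sarcf
    from . import strength as _str

    sarcf_total: Optional[int] = None
    sarcf_positive: Optional[bool] = None
    if sarcf is not None:
        score = sarcf if isinstance(sarcf, _sarcf.SarcFScore) else _sarcf.score_sarcf(sarcf)
        sarcf_total, sarcf_positive = score.total, score.positive

    strength_rec = _str.assess_strength(grip=grip, sts=sts, sex=patient.sex, cutoffs=cutoffs)

    quantity_verdict = StageVerdict.unknown
    sm_kg = smi = None
    if anthropometry is not None:
        mq = _bc.assess_quantity(patient, anthropometry, cutoffs=cutoffs)
        quantity_verdict = StageVerdict.low if mq.low else StageVerdict.not_low
        sm_kg, smi = mq.sm_kg, mq.smi

    performance_verdict = StageVerdict.unknown
    gait_speed = None
    if gait is not None:
        gait = _perf.assess_gait(gait, cutoffs=cutoffs)
        performance_verdict = StageVerdict.low if gait.low else StageVerdict.not_low
        gait_speed = gait.speed

    incomplete = tuple(
        name
        for name, verdict in (
            ("sarcf", StageVerdict.unknown if sarcf is None else StageVerdict.not_low),
            ("strength", strength_rec.verdict),
            ("quantity", quantity_verdict),
            ("performance", performance_verdict),
        )
        if verdict is StageVerdict.unknown
    )

    return SarcopeniaAssessment(
        patient_id=patient.patient_id,
        sarcf_total=sarcf_total,
        sarcf_positive=sarcf_positive,
        strength=strength_rec.verdict,
        quantity=quantity_verdict,
        performance=performance_verdict,
        grade=classify(strength_rec.verdict, quantity_verdict, performance_verdict),
        incomplete_flags=incomplete,
        grip_best_kg=strength_rec.grip.best if strength_rec.grip is not None else None,
        sts_best_s=strength_rec.sts.best if strength_rec.sts is not None else None,
        sm_kg=sm_kg,
        smi_kg_m2=smi,
        gait_speed_m_s=gait_speed,
    )
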