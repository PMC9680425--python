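"""Muscle-quantity stage: anthropometric skeletal-muscle-mass estimation.

Limb circumferences are corrected for subcutaneous fat with the matching
skinfold — corrected girth = circumference − π · skinfold — giving a
muscle-girth proxy.  Total skeletal muscle mass (SM, kg) is then
estimated with Lee's anthropometric prediction model:

    SM = Ht · (0.00744·CAG² + 0.00088·CTG² + 0.00441·CCG²)
         + 2.4·sex − 0.048·age + race + 7.8

with Ht in meters, corrected arm/thigh/calf girths (CAG/CTG/CCG) in cm,
sex coded male=1 / female=0, age in years, and a race term of 0
(white or Hispanic), +1.1 (Black) or −2.0 (Asian).

SM is normalized by height squared into a skeletal muscle mass index
(SMI, kg/m²) and compared against the sex-specific low-muscle-quantity
cut-offs (< 15 kg/m² men, < 12 kg/m² women).  Those cut-offs were
derived from DXA lean mass, not skeletal muscle mass; the pairing can
overestimate sarcopenia and reports carry that caveat.

Unit convention: skinfolds are entered in mm (caliper convention) and
converted to cm inside :func:`corrected_girth` — the single place the
conversion happens.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field

from .config import Cutoffs, DEFAULT_CUTOFFS
from .core_model import Ethnicity, Patient, Sex

#: race-term offsets of the muscle-mass model, kg
ETHNICITY_TERM_KG: dict[Ethnicity, float] = {
    Ethnicity.white_hispanic: 0.0,
    Ethnicity.black: 1.1,
    Ethnicity.asian: -2.0,
}


class Anthropometry(BaseModel):
    """Raw tape-and-caliper measurements.

    The biceps skinfold is collected and stored for completeness but is
    not used by the muscle-mass estimate (the model corrects the arm
    girth with the triceps skinfold only).
    """

    model_config = ConfigDict(frozen=True)

    arm_circ: float = Field(gt=0, description="relaxed arm circumference, cm")
    thigh_circ: float = Field(gt=0, description="thigh circumference, cm")
    calf_circ: float = Field(gt=0, description="calf circumference, cm")
    biceps_skf: float = Field(gt=0, description="biceps skinfold, mm")
    triceps_skf: float = Field(gt=0, description="triceps skinfold, mm")
    thigh_skf: float = Field(gt=0, description="thigh skinfold, mm")
    calf_skf: float = Field(gt=0, description="calf skinfold, mm")


class MuscleQuantity(BaseModel):
    """Derived muscle-quantity record with all intermediates retained."""

    model_config = ConfigDict(frozen=True)

    cag: float = Field(gt=0, description="corrected arm girth, cm")
    ctg: float = Field(gt=0, description="corrected thigh girth, cm")
    ccg: float = Field(gt=0, description="corrected calf girth, cm")
    sm_kg: float = Field(description="estimated total skeletal muscle mass, kg")
    smi: float = Field(gt=0, description="skeletal muscle mass index, kg/m2")
    low: bool


def corrected_girth(circumference_cm: float, skinfold_mm: float) -> float:
    """Fat-corrected limb girth: circumference − π · skinfold.

    The skinfold is converted from mm to cm here; no other operation
    touches units.
    """
    if circumference_cm <= 0:
        raise ValueError("circumference must be positive")
    if skinfold_mm < 0:
        raise ValueError("skinfold must be non-negative")
    girth = circumference_cm - math.pi * (skinfold_mm / 10.0)
    if girth <= 0:
        raise ValueError(
            f"skinfold exceeds limb girth (circumference {circumference_cm} cm, "
            f"skinfold {skinfold_mm} mm)"
        )
    return girth


def lee_sm_mass(
    height_m: float,
    cag_cm: float,
    ctg_cm: float,
    ccg_cm: float,
    sex: Sex,
    age_years: float,
    ethnicity: Ethnicity = Ethnicity.white_hispanic,
) -> float:
    """Estimate total skeletal muscle mass (kg); no internal rounding."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    if min(cag_cm, ctg_cm, ccg_cm) <= 0:
        raise ValueError("corrected girths must be positive")
    girth_term = 0.00744 * cag_cm**2 + 0.00088 * ctg_cm**2 + 0.00441 * ccg_cm**2
    sex_term = 2.4 if sex is Sex.male else 0.0
    return height_m * girth_term + sex_term - 0.048 * age_years + ETHNICITY_TERM_KG[ethnicity] + 7.8


def smi(sm_kg: float, height_m: float) -> float:
    """Skeletal muscle mass index: SM / height², kg/m²."""
    if sm_kg <= 0:
        raise ValueError("skeletal muscle mass must be positive")
    if height_m <= 0:
        raise ValueError("height must be positive")
    return sm_kg / height_m**2


def low_muscle_quantity(smi_kg_m2: float, sex: Sex, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> bool:
    """Low muscle quantity: SMI strictly below the sex-specific cut-off."""
    cutoff = cutoffs.smi_low_male_kg_m2 if sex is Sex.male else cutoffs.smi_low_female_kg_m2
    return smi_kg_m2 < cutoff


def assess_quantity(
    patient: Patient,
    anthro: Anthropometry,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> MuscleQuantity:
    """Full muscle-quantity chain: correct girths, estimate SM, index, classify.

    Girth/skinfold pairing: arm↔triceps, thigh↔thigh, calf↔calf.
    """
    cag = corrected_girth(anthro.arm_circ, anthro.triceps_skf)
    ctg = corrected_girth(anthro.thigh_circ, anthro.thigh_skf)
    ccg = corrected_girth(anthro.calf_circ, anthro.calf_skf)
    sm = lee_sm_mass(patient.height, cag, ctg, ccg, patient.sex, patient.age, patient.ethnicity)
    index = smi(sm, patient.height)
    return MuscleQuantity(
        cag=cag,
        ctg=ctg,
        ccg=ccg,
        sm_kg=sm,
        smi=index,
        low=low_muscle_quantity(index, patient.sex, cutoffs),
    )
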