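"""Muscle-quantity stage: girth correction, the muscle-mass model, SMI
and the low-quantity cut-offs."""

import math

import numpy as np
import pytest

from sarcoscreen import (
    Anthropometry,
    Ethnicity,
    Patient,
    Sex,
    assess_quantity,
    corrected_girth,
    lee_sm_mass,
    low_muscle_quantity,
    smi,
)

# race-term offsets (kg) of the model, restated independently here
_ETH_TERM = {Ethnicity.white_hispanic: 0.0, Ethnicity.black: 1.1, Ethnicity.asian: -2.0}


def oracle_sm(height, cag, ctg, ccg, sex, age, ethnicity=Ethnicity.white_hispanic):
    """Term-by-term spreadsheet-style evaluation of the prediction model."""
    t_arm = 0.00744 * cag * cag
    t_thigh = 0.00088 * ctg * ctg
    t_calf = 0.00441 * ccg * ccg
    t_sex = 2.4 if sex is Sex.male else 0.0
    t_age = -0.048 * age
    return height * (t_arm + t_thigh + t_calf) + t_sex + t_age + _ETH_TERM[ethnicity] + 7.8


class TestCorrectedGirth:
    @pytest.mark.parametrize(
        ("circ", "skf", "expected"),
        [
            (30.0, 0.0, 30.0),  # zero skinfold: identity
            (30.0, 10.0, 30.0 - math.pi),  # 26.8584
            (35.0, 8.0, 35.0 - math.pi * 0.8),  # 32.4867
        ],
    )
    def test_values(self, circ, skf, expected):
        assert corrected_girth(circ, skf) == pytest.approx(expected, abs=1e-4)

    def test_skinfold_exceeding_girth_rejected(self):
        with pytest.raises(ValueError, match="skinfold exceeds limb girth"):
            corrected_girth(3.0, 30.0)

    def test_correction_never_increases_girth(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            circ = rng.uniform(15, 60)
            skf = rng.uniform(0, 25)
            if circ - math.pi * skf / 10 <= 0:
                continue
            out = corrected_girth(circ, skf)
            assert out <= circ
            assert (out == circ) == (skf == 0)


class TestMuscleMassModel:
    WORKED = dict(height=1.70, cag=26.8584, ctg=44.2301, ccg=32.4867, age=70)

    def test_worked_patient(self):
        sm = lee_sm_mass(
            self.WORKED["height"],
            self.WORKED["cag"],
            self.WORKED["ctg"],
            self.WORKED["ccg"],
            Sex.male,
            self.WORKED["age"],
        )
        assert sm == pytest.approx(26.803, abs=0.01)

    def test_sex_term_additive(self):
        w = self.WORKED
        male = lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"], Sex.male, w["age"])
        female = lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"], Sex.female, w["age"])
        assert male - female == pytest.approx(2.4, abs=1e-12)

    def test_age_term_linear(self):
        w = self.WORKED
        at70 = lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"], Sex.male, 70)
        at71 = lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"], Sex.male, 71)
        assert at70 - at71 == pytest.approx(0.048, abs=1e-12)

    def test_matches_term_by_term_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            height = rng.uniform(1.45, 1.95)
            cag = rng.uniform(18, 36)
            ctg = rng.uniform(35, 60)
            ccg = rng.uniform(25, 42)
            sex = Sex.male if rng.random() < 0.5 else Sex.female
            age = int(rng.integers(18, 95))
            eth = list(Ethnicity)[int(rng.integers(0, 3))]
            assert lee_sm_mass(height, cag, ctg, ccg, sex, age, eth) == pytest.approx(
                oracle_sm(height, cag, ctg, ccg, sex, age, eth), abs=1e-9
            )

    def test_strictly_monotone_in_each_girth_and_height(self):
        w = self.WORKED
        base = lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"], Sex.male, w["age"])
        assert lee_sm_mass(w["height"], w["cag"] + 1, w["ctg"], w["ccg"], Sex.male, w["age"]) > base
        assert lee_sm_mass(w["height"], w["cag"], w["ctg"] + 1, w["ccg"], Sex.male, w["age"]) > base
        assert lee_sm_mass(w["height"], w["cag"], w["ctg"], w["ccg"] + 1, Sex.male, w["age"]) > base
        assert lee_sm_mass(w["height"] + 0.05, w["cag"], w["ctg"], w["ccg"], Sex.male, w["age"]) > base


class TestSmiAndCutoffs:
    @pytest.mark.parametrize(
        ("sm", "height", "expected"),
        [(26.803, 1.70, 9.274), (15.0, 1.0, 15.0), (0.0001, 2.0, 0.000025)],
    )
    def test_smi(self, sm, height, expected):
        assert smi(sm, height) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        ("value", "sex", "low"),
        [
            (9.274, Sex.male, True),
            (15.0, Sex.male, False),  # boundary is NOT low
            (14.999, Sex.male, True),
            (12.5, Sex.female, False),
            (12.0, Sex.female, False),
            (11.999, Sex.female, True),
        ],
    )
    def test_low_quantity_strict_boundary(self, value, sex, low):
        assert low_muscle_quantity(value, sex) is low

    @pytest.mark.parametrize(("sex", "cutoff"), [(Sex.male, 15.0), (Sex.female, 12.0)])
    def test_boundary_recovery_by_bisection(self, sex, cutoff):
        lo, hi = 1.0, 30.0  # low at lo, not low at hi
        for _ in range(60):
            mid = (lo + hi) / 2
            if low_muscle_quantity(mid, sex):
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(cutoff, abs=1e-9)


class TestAssessQuantity:
    def test_worked_chain(self, male_70, worked_anthropometry):
        mq = assess_quantity(male_70, worked_anthropometry)
        assert mq.cag == pytest.approx(26.8584, abs=1e-4)
        assert mq.ctg == pytest.approx(44.2301, abs=1e-4)
        assert mq.ccg == pytest.approx(32.4867, abs=1e-4)
        assert mq.sm_kg == pytest.approx(26.80, abs=0.01)
        assert mq.smi == pytest.approx(9.27, abs=0.01)
        assert mq.low is True

    def test_arm_uses_triceps_not_biceps_skinfold(self, male_70, worked_anthropometry):
        """Changing the biceps skinfold must not move the estimate."""
        other = worked_anthropometry.model_copy(update={"biceps_skf": 25.0})
        assert assess_quantity(male_70, other) == assess_quantity(male_70, worked_anthropometry)

    def test_excessive_skinfold_propagates_error(self, male_70, worked_anthropometry):
        bad = worked_anthropometry.model_copy(update={"calf_skf": 200.0})
        with pytest.raises(ValueError, match="skinfold exceeds limb girth"):
            assess_quantity(male_70, bad)
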