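"""Muscle-strength stage: handgrip dynamometry and five-repetition
sit-to-stand.

Handgrip follows the Southampton protocol (seated, forearms supported,
wrist neutral, vocal encouragement, up to three trials per hand
alternating sides); the maximal force over all trials, both hands
pooled, is the score.  Low strength is a best grip strictly below
27 kg for men or 16 kg for women.

The five-repetition sit-to-stand times five chair rises with arms
crossed; up to three timed repetitions (after two practice trials,
which are not recorded) and the best (minimum) time is the score.  Low
strength is a best time strictly above 15 s, for both sexes.

When both tests were administered the stage verdict takes the worst
result: the stage is low if either test is low.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import Cutoffs, DEFAULT_CUTOFFS
from .core_model import Sex, StageVerdict

logger = logging.getLogger(__name__)


class Hand(str, enum.Enum):
    left = "left"
    right = "right"


class GripTrial(BaseModel):
    model_config = ConfigDict(frozen=True)

    hand: Hand
    force: float = Field(ge=0, description="grip force in kg")


class GripSession(BaseModel):
    """Handgrip trials; at most three per hand.

    Fewer than three trials on a hand is accepted (field conditions vary)
    but logged as a protocol deviation.
    """

    model_config = ConfigDict(frozen=True)

    trials: tuple[GripTrial, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_trial_counts(self) -> "GripSession":
        for hand in Hand:
            count = sum(1 for t in self.trials if t.hand is hand)
            if count > 3:
                raise ValueError(f"more than 3 grip trials on {hand.value} hand")
            if 0 < count < 3:
                logger.warning("only %d grip trial(s) on %s hand (protocol asks 3)", count, hand.value)
        return self

    @property
    def best(self) -> float:
        return best_grip(self)


class SitToStandResult(BaseModel):
    """Timed five-repetition sit-to-stand; one to three repetitions."""

    model_config = ConfigDict(frozen=True)

    times: tuple[float, ...] = Field(min_length=1, max_length=3, description="seconds per 5-rep trial")

    @model_validator(mode="after")
    def _check_positive(self) -> "SitToStandResult":
        if any(t <= 0 for t in self.times):
            raise ValueError("sit-to-stand times must be positive")
        return self

    @property
    def best(self) -> float:
        return best_sts(self)


class StrengthRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    grip: Optional[GripSession] = None
    sts: Optional[SitToStandResult] = None
    verdict: StageVerdict


def best_grip(session: GripSession) -> float:
    """Maximal grip force (kg) over all trials, both hands pooled."""
    if not session.trials:
        raise ValueError("no grip trials")
    return max(t.force for t in session.trials)


def low_grip(best: float, sex: Sex, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> bool:
    """Low grip strength: strictly below the sex-specific cut-off.

    A measurement exactly at the cut-off is NOT low.
    """
    cutoff = cutoffs.grip_low_male_kg if sex is Sex.male else cutoffs.grip_low_female_kg
    return best < cutoff


def best_sts(result: SitToStandResult) -> float:
    """Best (minimum) time in seconds over the recorded repetitions."""
    if not result.times:
        raise ValueError("no sit-to-stand times")
    return min(result.times)


def low_sts(best: float, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> bool:
    """Low strength by sit-to-stand: strictly above the cut-off, sex-independent."""
    return best > cutoffs.sts_slow_s


def assess_strength(
    grip: Optional[GripSession] = None,
    sts: Optional[SitToStandResult] = None,
    *,
    sex: Sex,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> StrengthRecord:
    """Reduce the administered strength tests to a stage verdict.

    Worst-of-two rule: if both tests were administered the verdict is low
    when either is low.  With no test administered the verdict is unknown.
    """
    flags = []
    if grip is not None:
        flags.append(low_grip(best_grip(grip), sex, cutoffs))
    if sts is not None:
        flags.append(low_sts(best_sts(sts), cutoffs))
    if not flags:
        verdict = StageVerdict.unknown
    elif any(flags):
        verdict = StageVerdict.low
    else:
        verdict = StageVerdict.not_low
    return StrengthRecord(grip=grip, sts=sts, verdict=verdict)
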