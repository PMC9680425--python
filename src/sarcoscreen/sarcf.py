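"""SARC-F case-finding questionnaire scoring.

SARC-F asks about five everyday functions: Strength (lifting/carrying
about 10 lb / 4.5 kg), Assistance walking, Rising from a chair, Climbing
a flight of stairs, and Falls in the past year.  Each item contributes
0-2 points; the total ranges 0 (best) to 10 (worst) and a total of 4 or
more is a positive screen.  The falls item is banded from the raw count:
no falls scores 0, one to three falls scores 1, four or more falls
scores 2.

The raw fall count (not the band) is what the questionnaire captures
here, so the banding rule itself is part of the engine and testable.
A response with any unanswered difficulty item does not score: a partial
SARC-F total is undefined.
"""

from __future__ import annotations

import enum

from pydantic import BaseModel, ConfigDict, Field

#: threshold for a positive case-finding screen (total >= this)
POSITIVITY_THRESHOLD = 4


class Difficulty(str, enum.Enum):
    """Per-item answer; ``worst`` is 'a lot of difficulty, (uses aids,) or
    unable to do it' — the exact wording varies by item, the points do not."""

    none = "none"
    some = "some"
    worst = "worst"


_DIFFICULTY_POINTS = {Difficulty.none: 0, Difficulty.some: 1, Difficulty.worst: 2}

#: Questionnaire display text for the strength item's load (not used in
#: any computation).
STRENGTH_ITEM_LOAD_TEXT = "10 pounds (approximately 4.5 kg)"


class SarcFResponse(BaseModel):
    model_config = ConfigDict(frozen=True)

    strength_difficulty: Difficulty
    walking_difficulty: Difficulty
    chair_transfer_difficulty: Difficulty
    stair_difficulty: Difficulty
    falls_last_year: int = Field(ge=0)


class SarcFScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_points: tuple[int, int, int, int, int]
    total: int = Field(ge=0, le=10)
    positive: bool


def falls_points(falls_last_year: int) -> int:
    """Band the past-year fall count into 0, 1 or 2 points."""
    if falls_last_year < 0:
        raise ValueError("falls_last_year must be non-negative")
    if falls_last_year == 0:
        return 0
    if falls_last_year <= 3:
        return 1
    return 2


def score_sarcf(response: SarcFResponse) -> SarcFScore:
    """Score a complete SARC-F response.

    Item order in ``item_points``: strength, walking, chair transfer,
    stairs, falls.
    """
    points = (
        _DIFFICULTY_POINTS[response.strength_difficulty],
        _DIFFICULTY_POINTS[response.walking_difficulty],
        _DIFFICULTY_POINTS[response.chair_transfer_difficulty],
        _DIFFICULTY_POINTS[response.stair_difficulty],
        falls_points(response.falls_last_year),
    )
    total = sum(points)
    return SarcFScore(item_points=points, total=total, positive=is_case_finding_positive(total))


def is_case_finding_positive(total: int) -> bool:
    """Positive screen iff total >= 4 (a total below 4 is negative)."""
    if not 0 <= total <= 10:
        raise ValueError(f"SARC-F total must be in [0, 10], got {total}")
    return total >= POSITIVITY_THRESHOLD
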