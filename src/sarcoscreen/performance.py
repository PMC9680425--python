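"""Physical-performance stage: the timed 15-foot gait-speed test.

The course defaults to exactly 15 ft = 4.572 m (≈ 4.6 m); speed is
course length over time.  Low physical performance — the severity
criterion — is a speed at or below the configured cut-off, by default
the EWGSOP2-recommended 0.8 m/s, inclusive.  Both the cut-off and the
course length are site-configurable (see :mod:`sarcoscreen.config`).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .config import Cutoffs, DEFAULT_CUTOFFS, FEET_15_IN_M


class GaitResult(BaseModel):
    """A timed walk; ``speed`` and ``low`` are filled by :func:`assess_gait`."""

    model_config = ConfigDict(frozen=True)

    course_length: float = Field(default=FEET_15_IN_M, gt=0, description="meters")
    time: float = Field(gt=0, description="seconds")
    speed: Optional[float] = Field(default=None, description="m/s, derived")
    low: Optional[bool] = None


def gait_speed(course_length_m: float, time_s: float) -> float:
    """Walking speed in m/s."""
    if course_length_m <= 0:
        raise ValueError("course length must be positive")
    if time_s <= 0:
        raise ValueError("gait time must be positive")
    return course_length_m / time_s


def low_performance(speed_m_s: float, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> bool:
    """Low performance iff speed ≤ cut-off (inclusive boundary)."""
    if speed_m_s <= 0:
        raise ValueError("speed must be positive")
    return speed_m_s <= cutoffs.gait_slow_m_per_s


def assess_gait(result: GaitResult, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> GaitResult:
    """Return a copy of ``result`` with speed and the low flag derived."""
    speed = gait_speed(result.course_length, result.time)
    return GaitResult(
        course_length=result.course_length,
        time=result.time,
        speed=speed,
        low=low_performance(speed, cutoffs),
    )
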