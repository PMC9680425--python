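"""The per-patient raw-record bundle shared by cohort generation and I/O."""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict

from .body_composition import Anthropometry
from .core_model import Patient
from .performance import GaitResult
from .sarcf import SarcFResponse
from .strength import GripSession, SitToStandResult


class PatientBundle(BaseModel):
    """One patient's demographics plus whatever stages were administered."""

    model_config = ConfigDict(frozen=True)

    patient: Patient
    sarcf: Optional[SarcFResponse] = None
    grip: Optional[GripSession] = None
    sts: Optional[SitToStandResult] = None
    anthropometry: Optional[Anthropometry] = None
    gait: Optional[GaitResult] = None
    intended_stratum: Optional[str] = None
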