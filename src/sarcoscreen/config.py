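"""Cut-off configuration.

All decision thresholds of the assessment engine live here so that a site
can override any of them from a YAML or JSON file.  The defaults are the
EWGSOP2 values the engine is built around:

* handgrip strength: low if strictly below 27 kg (men) / 16 kg (women)
* five-repetition sit-to-stand: low if strictly above 15 s (both sexes)
* skeletal muscle mass index: low if strictly below 15 kg/m2 (men) /
  12 kg/m2 (women)
* gait speed: low if at or below 0.8 m/s, over a 15 ft (4.572 m) course

The gait-speed cut-off and its inclusivity are the EWGSOP2 recommendation,
not a value the source rubric prints; it is therefore deliberately
configurable (``performance.cutoff_m_per_s``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

FEET_15_IN_M = 4.572  # exact: 15 ft x 0.3048 m/ft


@dataclass(frozen=True)
class Cutoffs:
    """Decision thresholds, with the EWGSOP2 defaults."""

    grip_low_male_kg: float = 27.0
    grip_low_female_kg: float = 16.0
    sts_slow_s: float = 15.0
    smi_low_male_kg_m2: float = 15.0
    smi_low_female_kg_m2: float = 12.0
    gait_slow_m_per_s: float = 0.8
    gait_course_m: float = FEET_15_IN_M

    def replace(self, **changes: float) -> "Cutoffs":
        return replace(self, **changes)


DEFAULT_CUTOFFS = Cutoffs()

# config-file key -> Cutoffs field
_KEY_MAP: dict[str, str] = {
    "strength.grip_male_kg": "grip_low_male_kg",
    "strength.grip_female_kg": "grip_low_female_kg",
    "strength.sts_s": "sts_slow_s",
    "quantity.smi_male_kg_m2": "smi_low_male_kg_m2",
    "quantity.smi_female_kg_m2": "smi_low_female_kg_m2",
    "performance.cutoff_m_per_s": "gait_slow_m_per_s",
    "performance.course_m": "gait_course_m",
}


def _flatten(prefix: str, node: Any, out: dict[str, float]) -> None:
    if isinstance(node, Mapping):
        for key, value in node.items():
            _flatten(f"{prefix}.{key}" if prefix else str(key), value, out)
    else:
        out[prefix] = float(node)


def cutoffs_from_mapping(data: Mapping[str, Any]) -> Cutoffs:
    """Build a :class:`Cutoffs` from a (possibly nested) mapping.

    Accepts dotted keys (``performance.cutoff_m_per_s``) or the same keys
    as nested sections.  Unknown keys raise ``KeyError`` rather than being
    silently ignored — a typo in a cut-off must not fall back to a default.
    """
    flat: dict[str, float] = {}
    _flatten("", data, flat)
    changes: dict[str, float] = {}
    for key, value in flat.items():
        field = _KEY_MAP.get(key)
        if field is None:
            raise KeyError(f"unknown configuration key: {key!r}")
        changes[field] = value
    return DEFAULT_CUTOFFS.replace(**changes)


def load_cutoffs(path: str | Path) -> Cutoffs:
    """Load cut-offs from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return DEFAULT_CUTOFFS
    return cutoffs_from_mapping(data)
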