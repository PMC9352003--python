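"""Comprehensive four-grade quality decision.

Decision flow combining the three appearance labels with the Brix grade:

* any surface defect        -> substandard (sweetness not consulted);
* no defect but oval shape  -> second class (sweetness not consulted);
* no defect, nearly round   -> excellent / first class / second class for
  high / medium / low Brix respectively.

The size grade (XL/L/M/S) rides along unchanged — it never influences the
quality grade.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError
from .vision import AppearanceResult

__all__ = ["GradeResult", "grade_apple", "QUALITY_GRADES"]

QUALITY_GRADES = ("excellent", "first_class", "second_class", "substandard")

_BRIX_TO_GRADE = {"high": "excellent", "medium": "first_class", "low": "second_class"}


@dataclass(frozen=True)
class GradeResult:
    quality_grade: str  # excellent | first_class | second_class | substandard
    size_grade: str  # extra_large | large | medium | small
    appearance: AppearanceResult
    brix_grade: str  # high | medium | low


def grade_apple(appearance: AppearanceResult, brix_grade: str) -> GradeResult:
    """Map (defect, shape, Brix) labels to the final quality grade."""
    if appearance.defect_label not in ("normal", "defective"):
        raise InvalidParameterError(f"unknown defect label {appearance.defect_label!r}")
    if appearance.shape_label not in ("nearly_round", "nearly_oval"):
        raise InvalidParameterError(f"unknown shape label {appearance.shape_label!r}")
    if brix_grade not in _BRIX_TO_GRADE:
        raise InvalidParameterError(f"unknown brix grade {brix_grade!r}")

    if appearance.defect_label == "defective":
        quality = "substandard"
    elif appearance.shape_label == "nearly_oval":
        quality = "second_class"
    else:
        quality = _BRIX_TO_GRADE[brix_grade]
    return GradeResult(
        quality_grade=quality,
        size_grade=appearance.size_label,
        appearance=appearance,
        brix_grade=brix_grade,
    )
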