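"""Brix (soluble-solids) grade thresholds for Red Fuji apples."""

from __future__ import annotations

from ..errors import InvalidParameterError

__all__ = ["classify_brix", "BRIX_HIGH_THRESHOLD", "BRIX_MEDIUM_THRESHOLD"]

#: national-standard reference: mature Fuji apples at >= 13% soluble solids
BRIX_HIGH_THRESHOLD = 13.0
BRIX_MEDIUM_THRESHOLD = 10.0


def classify_brix(brix: float) -> str:
    """Three-way sweetness grade: ``high`` at >= 13 °Brix, ``medium`` in
    [10, 13), ``low`` below 10."""
    if brix < 0:
        raise InvalidParameterError(f"Brix must be non-negative, got {brix}")
    if brix >= BRIX_HIGH_THRESHOLD:
        return "high"
    if brix >= BRIX_MEDIUM_THRESHOLD:
        return "medium"
    return "low"
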