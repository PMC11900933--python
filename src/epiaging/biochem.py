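"""Clinical-chemistry derived quantities: HOMA-IR and unit conversions.

HOMA-IR (homeostatic model assessment of insulin resistance) is
(fasting insulin [uIU/mL] * fasting glucose [mmol/L]) / 22.5.  Glucose
is converted from mg/dL with the exact molar factor 1/18.016 mmol/L per
mg/dL by default; the coarser rounded factor 0.06 seen in assay
documentation is available behind a compatibility flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GLUCOSE_MGDL_TO_MMOL",
    "GLUCOSE_MGDL_TO_MMOL_ROUNDED",
    "MetabolicPanel",
    "homa_ir",
    "glucose_mgdl_to_mmol",
    "glucose_mmol_to_mgdl",
]

#: Exact conversion, mmol/L per mg/dL (glucose molar mass 180.16 g/mol).
GLUCOSE_MGDL_TO_MMOL = 1.0 / 18.016
#: Rounded factor sometimes quoted in assay sensitivity footnotes.
GLUCOSE_MGDL_TO_MMOL_ROUNDED = 0.06


def _factor(rounded: bool) -> float:
    return GLUCOSE_MGDL_TO_MMOL_ROUNDED if rounded else GLUCOSE_MGDL_TO_MMOL


def glucose_mgdl_to_mmol(x: float, rounded_factor: bool = False) -> float:
    """Glucose mg/dL -> mmol/L."""
    if not (math.isfinite(x) and x >= 0):
        raise ValueError(f"glucose must be non-negative and finite, got {x}")
    return x * _factor(rounded_factor)


def glucose_mmol_to_mgdl(x: float, rounded_factor: bool = False) -> float:
    """Glucose mmol/L -> mg/dL (inverse of :func:`glucose_mgdl_to_mmol`)."""
    if not (math.isfinite(x) and x >= 0):
        raise ValueError(f"glucose must be non-negative and finite, got {x}")
    return x / _factor(rounded_factor)


def homa_ir(insulin_uiu_ml: float, glucose_mmol: float) -> float:
    """HOMA-IR: insulin [uIU/mL] * glucose [mmol/L] / 22.5, dimensionless."""
    for name, v in (("insulin", insulin_uiu_ml), ("glucose", glucose_mmol)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    return insulin_uiu_ml * glucose_mmol / 22.5


@dataclass(frozen=True)
class MetabolicPanel:
    """Fasting glucose (unit-tagged) and insulin for one subject."""

    glucose: float
    glucose_unit: str  # "mg/dL" | "mmol/L"
    insulin_uiu_ml: float

    def __post_init__(self) -> None:
        if self.glucose_unit not in ("mg/dL", "mmol/L"):
            raise ValueError(
                f"glucose unit must be 'mg/dL' or 'mmol/L', got {self.glucose_unit!r}")
        for name, v in (("glucose", self.glucose), ("insulin", self.insulin_uiu_ml)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    def glucose_mmol(self, rounded_factor: bool = False) -> float:
        if self.glucose_unit == "mmol/L":
            return self.glucose
        return glucose_mgdl_to_mmol(self.glucose, rounded_factor)

    def homa_ir(self, rounded_factor: bool = False) -> float:
        return homa_ir(self.insulin_uiu_ml, self.glucose_mmol(rounded_factor))
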