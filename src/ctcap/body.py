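"""Patient/phantom body measurements and unit handling.

A :class:`BodySpec` is the canonical (height cm, weight kg) record used
throughout the pipeline; BMI is derived, never stored independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidMeasurementError

CM_PER_INCH = 2.54
KG_PER_LB = 0.45359237


@dataclass(frozen=True)
class BodySpec:
    """Canonical body measurements: height in cm, weight in kg."""

    height_cm: float
    weight_kg: float

    def __post_init__(self):
        for label, value in (("height", self.height_cm), ("weight", self.weight_kg)):
            if not math.isfinite(value) or value <= 0:
                raise InvalidMeasurementError(f"{label} must be positive and finite, got {value!r}")

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m2."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @classmethod
    def from_bmi(cls, height_cm: float, bmi: float) -> "BodySpec":
        return cls(height_cm=height_cm, weight_kg=bmi * (height_cm / 100.0) ** 2)


def make_body_spec(height_value, height_unit: str, weight_value, weight_unit: str) -> BodySpec:
    """Build a :class:`BodySpec` from measurements in cm/m/ft+in and kg/lb.

    ``height_unit='ft_in'`` expects ``height_value`` as a ``(feet, inches)``
    pair.  Conversions use exactly 1 in = 2.54 cm and 1 lb = 0.45359237 kg.
    """
    if height_unit == "cm":
        height_cm = float(height_value)
    elif height_unit == "m":
        height_cm = 100.0 * float(height_value)
    elif height_unit == "ft_in":
        try:
            feet, inches = height_value
        except (TypeError, ValueError) as exc:
            raise InvalidMeasurementError("ft_in height must be a (feet, inches) pair") from exc
        if feet < 0 or inches < 0:
            raise InvalidMeasurementError("feet and inches must be non-negative")
        height_cm = (12.0 * float(feet) + float(inches)) * CM_PER_INCH
    else:
        raise InvalidMeasurementError(f"unknown height unit {height_unit!r}")

    if weight_unit == "kg":
        weight_kg = float(weight_value)
    elif weight_unit == "lb":
        weight_kg = float(weight_value) * KG_PER_LB
    else:
        raise InvalidMeasurementError(f"unknown weight unit {weight_unit!r}")

    return BodySpec(height_cm=height_cm, weight_kg=weight_kg)
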