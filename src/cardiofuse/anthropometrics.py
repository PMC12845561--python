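"""Body-surface-area and cardiac-index conversions.

Cardiac index (CI, L/min/m^2) is cardiac output (CO, L/min) normalized by
body surface area (BSA, m^2).  BSA uses the Mosteller estimate
``sqrt(height_cm * weight_kg / 3600)``.  The indirect CO pathway multiplies a
predicted CI back by the patient-specific BSA, so ``ci_from_co`` and
``co_indirect`` are exact inverses for a fixed BSA.

Inputs are strictly in cm and kg; no unit auto-detection is attempted, since
silent unit errors are the dominant real-world failure mode for BSA formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


__all__ = ["HemoValue", "bsa_mosteller", "ci_from_co", "co_indirect"]


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area in m^2.

    Parameters
    ----------
    height_cm : height in centimetres, > 0.
    weight_kg : weight in kilograms, > 0.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(
            f"height and weight must be positive, got ({height_cm}, {weight_kg})"
        )
    return math.sqrt(height_cm * weight_kg / 3600.0)


def ci_from_co(co_lpm: float, bsa_m2: float) -> float:
    """Cardiac index (L/min/m^2) = CO (L/min) / BSA (m^2)."""
    if bsa_m2 <= 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    return co_lpm / bsa_m2


def co_indirect(ci_pred: float, bsa_m2: float) -> float:
    """Reconstruct CO (L/min) from a predicted CI and patient BSA."""
    if bsa_m2 <= 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    return ci_pred * bsa_m2


@dataclass(frozen=True)
class HemoValue:
    """A consistent (CO, CI, BSA) triple; CO or CI may be derived.

    Invariant: when both co and ci are given, co == ci * bsa to 1e-9.
    """

    bsa: float
    co: float | None = None
    ci: float | None = None

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError("BSA must be positive")
        if self.co is None and self.ci is None:
            raise ValueError("at least one of co, ci required")
        if self.co is not None and self.co <= 0:
            raise ValueError("CO must be positive")
        if self.ci is not None and self.ci <= 0:
            raise ValueError("CI must be positive")
        if self.co is not None and self.ci is not None:
            if abs(self.co - self.ci * self.bsa) > 1e-9:
                raise ValueError(
                    f"inconsistent triple: co={self.co} != ci*bsa={self.ci * self.bsa}"
                )

    @property
    def co_value(self) -> float:
        return self.co if self.co is not None else co_indirect(self.ci, self.bsa)

    @property
    def ci_value(self) -> float:
        return self.ci if self.ci is not None else ci_from_co(self.co, self.bsa)
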