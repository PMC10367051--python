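"""Substituent reactivity descriptor from acid pKa differences.

The highest barriers of both hydrolytic steps pass through negatively
charged tetrahedral species; how well the warhead substituent stabilizes
that charge tracks the acidity of the corresponding substituted acetic
acid.  The descriptor converts a pKa difference into a free-energy shift,

    ΔΔG = (pKa_ref − pKa_sub) · RT·ln 10 ,

and the classifier adds that shift to the parent compound's
rate-determining barrier, converts the predicted barrier into a TST rate,
and compares it with an observed-rate floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R_KCAL
from .kinetics import eyring_rate
from .records import ValidationError

__all__ = [
    "SubstituentDescriptor",
    "delta_g_from_pka",
    "classify_warhead",
    "RATE_FLOOR_DEFAULT",
]

#: Default reactive/unreactive rate floor in s⁻¹, one order of magnitude
#: below the experimentally observed ~1e-3 s⁻¹ conversion of the parent
#: compound; the marginal band spans a further factor of ten below it.
RATE_FLOOR_DEFAULT = 1e-4

LN10 = math.log(10.0)


def delta_g_from_pka(pka_ref: float, pka_sub: float, T: float = 298.15) -> float:
    """Destabilization free energy (kcal/mol) from a pKa difference.

    Returns (pKa_ref − pKa_sub)·RT·ln 10; the familiar 1.36 kcal/mol per
    pKa unit is recovered at 298.15 K.
    """
    if not (math.isfinite(pka_ref) and math.isfinite(pka_sub)):
        raise ValueError("pKa values must be finite")
    return float((pka_ref - pka_sub) * R_KCAL * T * LN10)


@dataclass(frozen=True)
class SubstituentDescriptor:
    """pKa-based destabilization descriptor for one warhead substituent."""

    substituent_name: str
    pka_ref: float
    pka_sub: float
    delta_delta_g: float
    temperature: float = 298.15
    #: reference range (kcal/mol) the descriptor is compared against
    window: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        expected = delta_g_from_pka(self.pka_ref, self.pka_sub, self.temperature)
        if abs(expected - self.delta_delta_g) > 1e-6:
            raise ValidationError(
                f"delta_delta_g {self.delta_delta_g} is not "
                f"(pKa_ref − pKa_sub)·RT·ln10 = {expected:.6f} at "
                f"{self.temperature} K"
            )

    @classmethod
    def from_pkas(cls, substituent_name: str, pka_ref: float, pka_sub: float,
                  T: float = 298.15,
                  window: tuple[float, float] = (2.0, 8.0)) -> "SubstituentDescriptor":
        return cls(substituent_name, pka_ref, pka_sub,
                   delta_g_from_pka(pka_ref, pka_sub, T), T, window)

    @property
    def in_window(self) -> bool:
        lo, hi = self.window
        return lo <= self.delta_delta_g <= hi


def classify_warhead(descriptor: SubstituentDescriptor | float,
                     parent_rds_barrier: float,
                     observed_rate_floor: float = RATE_FLOOR_DEFAULT,
                     T: float = 303.15) -> str:
    """Classify a warhead as ``reactive``, ``unreactive`` or ``marginal``.

    The predicted rate-determining barrier is the parent barrier plus the
    descriptor's ΔΔG (a descriptor of 0 recovers the parent classification).
    ``reactive`` if the Eyring rate of the predicted barrier meets the
    floor, ``unreactive`` below a tenth of the floor, ``marginal`` between.
    """
    if parent_rds_barrier <= 0:
        raise ValueError("parent barrier must be positive")
    if observed_rate_floor <= 0:
        raise ValueError("rate floor must be positive")
    shift = (descriptor.delta_delta_g
             if isinstance(descriptor, SubstituentDescriptor) else float(descriptor))
    predicted = parent_rds_barrier + shift
    rate = eyring_rate(predicted, T)
    if rate >= observed_rate_floor:
        return "reactive"
    if rate < observed_rate_floor / 10.0:
        return "unreactive"
    return "marginal"


def predicted_rate(descriptor: SubstituentDescriptor | float,
                   parent_rds_barrier: float, T: float = 303.15) -> float:
    """TST rate (s⁻¹) of the shifted rate-determining barrier."""
    shift = (descriptor.delta_delta_g
             if isinstance(descriptor, SubstituentDescriptor) else float(descriptor))
    return eyring_rate(parent_rds_barrier + shift, T)
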