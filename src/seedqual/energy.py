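"""Label energy values from proximate composition.

Conversion factors follow Regulation (EU) No 1169/2011, Annex XIV: protein
and digestible carbohydrate 17 kJ/g (4 kcal/g), fat 37 kJ/g (9 kcal/g),
dietary fibre 8 kJ/g (2 kcal/g).  The kJ and kcal factors are fixed pairs set
by the regulation — they are deliberately not interconverted through 4.184.

Total sugars are a subset of digestible carbohydrate and are never added
separately.  The computation is basis-agnostic: it returns energy per 100 g
of whatever basis the composition is expressed on (dry matter in typical
seed-composition tables) and never rescales by moisture itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._round import round_half_up
from .model import ProximateComposition, ValidationError

__all__ = ["EnergyFactors", "REG_1169_2011", "energy_value", "energy_report"]


@dataclass(frozen=True)
class EnergyFactors:
    """(kJ/g, kcal/g) conversion factor pairs per component."""

    factors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REG_1169_2011.factors)
    )

    def __post_init__(self) -> None:
        for comp, (kj, kcal) in self.factors.items():
            if kj < 0 or kcal < 0:
                raise ValidationError(f"negative energy factor for {comp}")


#: The regulated factor set used for EU nutrition labelling.
REG_1169_2011 = EnergyFactors(
    factors={
        "protein": (17.0, 4.0),
        "digestible_carbohydrates": (17.0, 4.0),
        "fat_total": (37.0, 9.0),
        "dietary_fiber": (8.0, 2.0),
    }
)


def energy_value(
    comp: ProximateComposition, factors: EnergyFactors = REG_1169_2011
) -> tuple[float, float]:
    """Energy of a composition as ``(kJ/100 g, kcal/100 g)``, unrounded.

    Components of the composition without a factor (ash, salt, total sugars)
    contribute nothing.
    """
    kj = kcal = 0.0
    for component, (f_kj, f_kcal) in factors.factors.items():
        grams = getattr(comp, component, 0.0) or 0.0
        if grams < 0:
            raise ValidationError(f"negative component {component}")
        kj += f_kj * grams
        kcal += f_kcal * grams
    return kj, kcal


def energy_report(
    comp: ProximateComposition, factors: EnergyFactors = REG_1169_2011
) -> tuple[int, int]:
    """Label-style integers (half-up to 0 decimals)."""
    kj, kcal = energy_value(comp, factors)
    return int(round_half_up(kj, 0)), int(round_half_up(kcal, 0))
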