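"""Lipid nutritional-quality indices computed from a fatty-acid profile.

Five dimensionless indices, all on the %-of-total-FA basis:

* ``PUFA/SFA`` — (DiUFA + TriUFA + TetraUFA + higher) / SFA.
* ``n-6/n-3`` — by default the explicit four-acid enumeration
  (C18:2 n-6 + C18:3 n-6) / (C18:3 n-3 + C18:4 n-3); optionally the full
  family sums.
* ``AI`` (atherogenicity index) — (C12:0 + 4 C14:0 + C16:0) / UFA.
* ``TI`` (thrombogenicity index) —
  (C14:0 + C16:0 + C18:0) / (0.5 MUFA + 0.5 n-6 + 3 n-3 + n-3/n-6).
* ``h/H`` (hypo/hypercholesterolemic ratio) — eleven named unsaturated acids
  over (C14:0 + C16:0).

Acids absent from a profile contribute zero; a zero denominator raises
:class:`UndefinedRatioError`.  Raw double-precision values are returned;
table-style reporting rounds half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import round_half_up
from .fatty_acids import ClassShares, aggregate_shares
from .model import FattyAcidProfile

__all__ = [
    "LipidIndices",
    "UndefinedRatioError",
    "pufa_sfa",
    "n6_n3",
    "atherogenicity",
    "thrombogenicity",
    "hypo_hyper",
    "compute_indices",
]


class UndefinedRatioError(ZeroDivisionError):
    """An index denominator is zero for this profile."""


#: Acids of the h/H numerator: (carbons, double bonds, family).
HH_NUMERATOR = (
    (18, 1, "n-9"), (18, 1, "n-7"), (18, 2, "n-6"), (18, 3, "n-6"),
    (18, 3, "n-3"), (20, 3, "n-6"), (20, 4, "n-6"), (20, 5, "n-3"),
    (22, 4, "n-6"), (22, 5, "n-3"), (22, 6, "n-3"),
)


@dataclass(frozen=True)
class LipidIndices:
    """Results container; all values raw (unrounded) and dimensionless."""

    pufa_sfa_ratio: float
    n6_n3_ratio: float
    ai: float
    ti: float
    h_to_h: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Table-style report, half-up rounding."""
        return {
            "pufa_sfa_ratio": round_half_up(self.pufa_sfa_ratio, ndigits),
            "n6_n3_ratio": round_half_up(self.n6_n3_ratio, ndigits),
            "ai": round_half_up(self.ai, ndigits),
            "ti": round_half_up(self.ti, ndigits),
            "h_to_h": round_half_up(self.h_to_h, ndigits),
        }


def _shares(profile_or_shares) -> ClassShares:
    if isinstance(profile_or_shares, ClassShares):
        return profile_or_shares
    return aggregate_shares(profile_or_shares)


def pufa_sfa(profile_or_shares: FattyAcidProfile | ClassShares) -> float:
    """Polyunsaturated-to-saturated ratio."""
    s = _shares(profile_or_shares)
    if s.sfa == 0:
        raise UndefinedRatioError("PUFA/SFA undefined: SFA sum is zero")
    return s.pufa / s.sfa


def n6_n3(profile: FattyAcidProfile, family_sums: bool = False) -> float:
    """n-6/n-3 ratio.

    The default enumerates the four acids that dominate seed oils:
    (C18:2 n-6 + C18:3 n-6) / (C18:3 n-3 + C18:4 n-3).  With
    ``family_sums=True`` the full family sums are used instead.
    """
    if family_sums:
        s = aggregate_shares(profile)
        num, den = s.n6, s.n3
    else:
        num = profile.get_pct(18, 2, "n-6") + profile.get_pct(18, 3, "n-6")
        den = profile.get_pct(18, 3, "n-3") + profile.get_pct(18, 4, "n-3")
    if den == 0:
        raise UndefinedRatioError("n-6/n-3 undefined: n-3 sum is zero")
    return num / den


def atherogenicity(profile: FattyAcidProfile) -> float:
    """Atherogenicity index AI = (C12:0 + 4 C14:0 + C16:0) / UFA."""
    s = aggregate_shares(profile)
    if s.ufa == 0:
        raise UndefinedRatioError("AI undefined: UFA sum is zero")
    num = (
        profile.get_pct(12, 0)
        + 4.0 * profile.get_pct(14, 0)
        + profile.get_pct(16, 0)
    )
    return num / s.ufa


def thrombogenicity(profile: FattyAcidProfile) -> float:
    """Thrombogenicity index
    TI = (C14:0 + C16:0 + C18:0) / (0.5 MUFA + 0.5 n-6 + 3 n-3 + n-3/n-6)."""
    s = aggregate_shares(profile)
    if s.n6 == 0:
        raise UndefinedRatioError("TI undefined: n-6 sum is zero")
    den = 0.5 * s.mufa + 0.5 * s.n6 + 3.0 * s.n3 + s.n3 / s.n6
    if den == 0:
        raise UndefinedRatioError("TI undefined: denominator is zero")
    num = profile.get_pct(14, 0) + profile.get_pct(16, 0) + profile.get_pct(18, 0)
    return num / den


def hypo_hyper(profile: FattyAcidProfile) -> float:
    """Hypocholesterolemic/hypercholesterolemic ratio h/H."""
    den = profile.get_pct(14, 0) + profile.get_pct(16, 0)
    if den == 0:
        raise UndefinedRatioError("h/H undefined: C14:0 + C16:0 is zero")
    num = sum(profile.get_pct(c, d, fam) for c, d, fam in HH_NUMERATOR)
    return num / den


def compute_indices(
    profile: FattyAcidProfile, family_sums: bool = False
) -> LipidIndices:
    """All five indices for one profile."""
    return LipidIndices(
        pufa_sfa_ratio=pufa_sfa(profile),
        n6_n3_ratio=n6_n3(profile, family_sums=family_sums),
        ai=atherogenicity(profile),
        ti=thrombogenicity(profile),
        h_to_h=hypo_hyper(profile),
    )
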