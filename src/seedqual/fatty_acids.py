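"""Fatty-acid classification, class aggregation and basis conversion.

Classification is a pure function of the double-bond count: 0 saturated
(SFA), 1 monounsaturated (MUFA), and >= 2 polyunsaturated (PUFA), further
split into di-, tri-, tetra- (etc.) unsaturated classes.  Class shares are
computed from the records as given — never renormalised to 100 — so that
index values derived from published tables reproduce the printed numbers.

Basis conversion links the chromatogram basis (% of total FA) to the seed
basis (g/100 g dry matter) through the total-fat content:
``g = pct * total_fat_pct_dm / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .model import FattyAcidProfile, FattyAcidRecord, ValidationError

__all__ = [
    "ClassShares",
    "classify",
    "aggregate_shares",
    "pct_to_g_dm",
    "g_dm_to_pct",
    "convert_profile_to_g_dm",
]

_POLY_NAMES = {2: "DiUFA", 3: "TriUFA", 4: "TetraUFA", 5: "PentaUFA", 6: "HexaUFA"}


def classify(record: FattyAcidRecord | "object") -> str:
    """Class label of a fatty acid: SFA, MUFA, DiUFA, TriUFA, TetraUFA, ...

    Accepts a record or a bare notation; depends only on the double-bond
    count.
    """
    notation = getattr(record, "notation", record)
    db = notation.double_bonds
    if db == 0:
        return "SFA"
    if db == 1:
        return "MUFA"
    return _POLY_NAMES.get(db, f"{db}-UFA")


@dataclass
class ClassShares:
    """Aggregate class shares of one profile (all in the profile's basis).

    ``ufa = mufa + pufa`` and ``pufa = di + tri + tetra + higher`` hold
    exactly by construction.  ``n3``/``n6`` sum only acids whose family is
    explicitly n-3/n-6; acids with an unspecified family (e.g. C20:2 in seed
    oils) count toward the unsaturation classes but not toward a family.
    """

    sfa: float = 0.0
    mufa: float = 0.0
    di_ufa: float = 0.0
    tri_ufa: float = 0.0
    tetra_ufa: float = 0.0
    higher_ufa: float = 0.0
    n3: float = 0.0
    n6: float = 0.0
    basis: str = "pct_total_fa"

    @property
    def pufa(self) -> float:
        return self.di_ufa + self.tri_ufa + self.tetra_ufa + self.higher_ufa

    @property
    def ufa(self) -> float:
        return self.mufa + self.pufa

    @property
    def total(self) -> float:
        return self.sfa + self.ufa

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "basis"}
        d.update(pufa=self.pufa, ufa=self.ufa, total=self.total)
        return d


def aggregate_shares(
    profile: FattyAcidProfile,
    basis: str = "pct_total_fa",
    family_overrides: dict[str, str] | None = None,
) -> ClassShares:
    """Sum class and family shares over a profile.

    ``basis`` selects the abundance field (``"pct_total_fa"`` or
    ``"g_per_100g_dm"``).  ``family_overrides`` maps notation keys (e.g.
    ``"C20:2"``) to a family for callers who want unassigned acids counted in
    a family sum; by default they are left out.
    """
    if not profile.records:
        raise ValidationError(f"{profile.sample_id}: empty profile")
    shares = ClassShares(basis=basis)
    overrides = family_overrides or {}
    for rec in profile.records:
        value = getattr(rec, basis)
        if value is None:
            raise ValidationError(
                f"{profile.sample_id}: {rec.common_name} has no {basis} value"
            )
        label = classify(rec)
        if label == "SFA":
            shares.sfa += value
        elif label == "MUFA":
            shares.mufa += value
        elif label == "DiUFA":
            shares.di_ufa += value
        elif label == "TriUFA":
            shares.tri_ufa += value
        elif label == "TetraUFA":
            shares.tetra_ufa += value
        else:
            shares.higher_ufa += value
        family = overrides.get(rec.notation.key, rec.notation.family)
        if family == "n-3":
            shares.n3 += value
        elif family == "n-6":
            shares.n6 += value
    return shares


def pct_to_g_dm(pct_total_fa: float, total_fat_pct_dm: float) -> float:
    """Convert a %-of-total-FA share to g/100 g dry matter."""
    if pct_total_fa < 0 or total_fat_pct_dm < 0:
        raise ValidationError("abundances and fat content must be >= 0")
    return pct_total_fa * total_fat_pct_dm / 100.0


def g_dm_to_pct(g_per_100g_dm: float, total_fat_pct_dm: float) -> float:
    """Inverse of :func:`pct_to_g_dm`; errors when the fat content is zero."""
    if g_per_100g_dm < 0 or total_fat_pct_dm < 0:
        raise ValidationError("abundances and fat content must be >= 0")
    if total_fat_pct_dm == 0:
        raise ValidationError("cannot convert to %-share with zero total fat")
    return g_per_100g_dm * 100.0 / total_fat_pct_dm


def convert_profile_to_g_dm(profile: FattyAcidProfile) -> FattyAcidProfile:
    """Return a copy of ``profile`` with ``g_per_100g_dm`` filled in for every
    record from the profile's total-fat content."""
    if profile.total_fat_pct_dm is None:
        raise ValidationError(
            f"{profile.sample_id}: total_fat_pct_dm required for conversion"
        )
    records = [
        FattyAcidRecord(
            common_name=r.common_name,
            notation=r.notation,
            pct_total_fa=r.pct_total_fa,
            g_per_100g_dm=pct_to_g_dm(r.pct_total_fa, profile.total_fat_pct_dm),
        )
        for r in profile.records
    ]
    return FattyAcidProfile(
        sample_id=profile.sample_id,
        records=records,
        total_fat_pct_dm=profile.total_fat_pct_dm,
    )
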