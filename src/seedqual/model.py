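"""Domain types for seed composition data.

The central objects are fatty-acid profiles (abundances as % of total fatty
acids, optionally also as g/100 g seed dry matter), amino-acid profiles
(g/100 g dry matter plus the crude-protein content they sit in), proximate
composition (the macronutrient panel of a nutrition label) and essential
amino-acid reference patterns (requirements in g/100 g protein).

Fatty acids are identified by the shorthand lipid notation ``C<carbons>:<double
bonds>`` followed by an optional omega-family token, e.g. ``C18:3 n-3`` for
alpha-linolenic acid.  The parser accepts the typographic dialects found in
journal tables ("n − 3" with a unicode minus, "n-3", "ω-3") and canonicalises
to "n-3".
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "UNSPECIFIED",
    "FAMILIES",
    "AA_CODES",
    "AA_ALIASES",
    "FattyAcidNotation",
    "FattyAcidRecord",
    "FattyAcidProfile",
    "AminoAcidProfile",
    "ProximateComposition",
    "ReferencePattern",
    "NotationParseError",
    "ValidationError",
    "parse_fa_notation",
    "format_fa_notation",
    "builtin_pattern",
]

#: Sentinel family for acids whose omega family is not stated (e.g. C20:1).
UNSPECIFIED = "unspecified"

#: Omega families that occur in seed-oil work.
FAMILIES = frozenset({"n-3", "n-6", "n-7", "n-9"})

#: The 18 amino acids accepted in profiles (three-letter codes).
AA_CODES = (
    "Lys", "Met", "Cys", "Asp", "Thr", "Ser", "Glu", "Pro", "Gly",
    "Ala", "Val", "Ile", "Leu", "Tyr", "Phe", "His", "Arg", "Trp",
)

#: Analytical aliases: acid hydrolysis oxidises Cys/Met, so labs report them
#: as cysteic acid and methionine sulphone.
AA_ALIASES = {
    "cysteic acid": "Cys",
    "methionine sulphone": "Met",
    "methionine sulfone": "Met",
}


class NotationParseError(ValueError):
    """A fatty-acid shorthand string could not be parsed."""


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


# "C18:1 n − 7 (11 cis)" and friends.  Minus may be ASCII '-', unicode
# minus U+2212 or en-dash; 'ω' is accepted in place of 'n'.
_NOTATION_RE = re.compile(
    r"""^\s*C\s*(?P<carbons>\d+)\s*:\s*(?P<db>\d+)
        (?:\s*(?P<fam>[nω])\s*[-−–]\s*(?P<k>\d+))?
        (?:\s*\(\s*(?P<note>[^)]*?)\s*\))?
        \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class FattyAcidNotation:
    """Structured shorthand lipid notation.

    ``family`` is one of :data:`FAMILIES` or :data:`UNSPECIFIED`; a family can
    only be carried by an unsaturated acid.
    """

    carbons: int
    double_bonds: int
    family: str = UNSPECIFIED
    isomer_note: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.carbons <= 40:
            raise ValidationError(
                f"chain length {self.carbons} outside the plausible 1..40 range"
            )
        if self.double_bonds < 0:
            raise ValidationError("double_bonds must be >= 0")
        if self.family not in FAMILIES and self.family != UNSPECIFIED:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family != UNSPECIFIED and self.double_bonds < 1:
            raise ValidationError(
                f"saturated acid C{self.carbons}:0 cannot carry family {self.family}"
            )

    @property
    def key(self) -> str:
        """Canonical text form (without the isomer note) used as a map key."""
        s = f"C{self.carbons}:{self.double_bonds}"
        if self.family != UNSPECIFIED:
            s += f" {self.family}"
        return s

    def __str__(self) -> str:
        return format_fa_notation(self)


def parse_fa_notation(text: str) -> FattyAcidNotation:
    """Parse shorthand such as ``"C18:3 n − 3"`` or ``"C18:1 n-7 (11 cis)"``.

    All three family-token dialects ("n − k" with unicode minus, "n-k",
    "ω-k") parse identically; a missing token yields ``family=UNSPECIFIED``.
    """
    m = _NOTATION_RE.match(text)
    if m is None:
        raise NotationParseError(f"cannot parse fatty-acid notation {text!r}")
    family = UNSPECIFIED if m.group("fam") is None else f"n-{m.group('k')}"
    note = m.group("note") or None
    return FattyAcidNotation(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("db")),
        family=family,
        isomer_note=note,
    )


def format_fa_notation(n: FattyAcidNotation) -> str:
    """Canonical text form, e.g. ``"C18:1 n-7 (11 cis)"``."""
    s = n.key
    if n.isomer_note:
        s += f" ({n.isomer_note})"
    return s


@dataclass
class FattyAcidRecord:
    """One fatty acid in a profile.

    ``pct_total_fa`` is the share of total fatty acids in percent (the FAME
    chromatogram basis); ``g_per_100g_dm`` is the optional mass basis per
    100 g seed dry matter.
    """

    common_name: str
    notation: FattyAcidNotation
    pct_total_fa: float
    g_per_100g_dm: float | None = None

    def __post_init__(self) -> None:
        if self.pct_total_fa < 0:
            raise ValidationError(
                f"{self.common_name}: pct_total_fa must be >= 0"
            )
        if self.g_per_100g_dm is not None and self.g_per_100g_dm < 0:
            raise ValidationError(
                f"{self.common_name}: g_per_100g_dm must be >= 0"
            )


@dataclass
class FattyAcidProfile:
    """All fatty-acid records of one sample, plus the total-fat context.

    ``total_fat_pct_dm`` (total fat as % of dry matter) is the bridge between
    the %-of-total-FA basis and the g/100 g DM basis.
    """

    sample_id: str
    records: list[FattyAcidRecord] = field(default_factory=list)
    total_fat_pct_dm: float | None = None

    #: Slack on the sum-to-100 check; chromatogram tables round each row.
    SUM_TOLERANCE = 0.5

    def __post_init__(self) -> None:
        keys = [r.notation.key for r in self.records]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValidationError(
                f"{self.sample_id}: duplicate fatty acid(s) {sorted(dupes)}"
            )
        total = self.total_pct
        if self.records and total > 100 + self.SUM_TOLERANCE:
            raise ValidationError(
                f"{self.sample_id}: shares sum to {total:.2f} > 100"
            )
        if self.records and total < 95:
            warnings.warn(
                f"{self.sample_id}: shares sum to {total:.2f} < 95 %; "
                "profile may be incomplete",
                stacklevel=2,
            )

    @property
    def total_pct(self) -> float:
        return float(sum(r.pct_total_fa for r in self.records))

    def get_pct(
        self,
        carbons: int,
        double_bonds: int,
        family: str | None = None,
    ) -> float:
        """Summed %-share of acids matching the given structure; 0 if absent.

        ``family=None`` matches any family; pass an explicit family string to
        require it (acids with an unspecified family then do not match).
        """
        total = 0.0
        for r in self.records:
            n = r.notation
            if n.carbons != carbons or n.double_bonds != double_bonds:
                continue
            if family is not None and n.family != family:
                continue
            total += r.pct_total_fa
        return total

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AminoAcidProfile:
    """Amino-acid contents of one sample in g/100 g dry matter.

    ``protein_pct_dm`` is the crude-protein content (% of DM) that the
    per-protein conversion divides by.  Contents may exceed the protein mass
    fraction by up to 25 % in sum: hydrolysis adds water mass and crude
    protein is an N-based estimate, so exact closure is impossible.
    """

    sample_id: str
    contents_dm: dict[str, float] = field(default_factory=dict)
    protein_pct_dm: float | None = None

    CLOSURE_SLACK = 0.25

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for code, value in self.contents_dm.items():
            canonical = AA_ALIASES.get(code.strip().lower(), code.strip())
            canonical = canonical[:1].upper() + canonical[1:].lower() \
                if len(canonical) <= 3 else canonical
            if canonical not in AA_CODES:
                raise ValidationError(
                    f"{self.sample_id}: unknown amino-acid code {code!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"{self.sample_id}: negative content for {canonical}"
                )
            if canonical in clean:
                raise ValidationError(
                    f"{self.sample_id}: duplicate amino acid {canonical}"
                )
            clean[canonical] = float(value)
        self.contents_dm = clean
        if self.protein_pct_dm is not None:
            total = sum(clean.values())
            ceiling = self.protein_pct_dm * (1 + self.CLOSURE_SLACK)
            if total > ceiling:
                raise ValidationError(
                    f"{self.sample_id}: amino-acid sum {total:.2f} exceeds "
                    f"protein x {1 + self.CLOSURE_SLACK} = {ceiling:.2f}"
                )


@dataclass
class ProximateComposition:
    """Macronutrient panel of one sample, each component in % of dry matter.

    ``dry_matter_pct`` is on the as-is basis.  Missing analytes default to 0
    so that energy computation treats absence as zero contribution.
    """

    sample_id: str = ""
    protein: float = 0.0
    digestible_carbohydrates: float = 0.0
    total_sugars: float = 0.0
    dietary_fiber: float = 0.0
    fat_total: float = 0.0
    ash: float = 0.0
    salt: float = 0.0
    dry_matter_pct: float | None = None

    _COMPONENTS = (
        "protein", "digestible_carbohydrates", "total_sugars",
        "dietary_fiber", "fat_total", "ash", "salt",
    )
    MASS_TOLERANCE = 0.5

    def __post_init__(self) -> None:
        for name in self._COMPONENTS:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} = {v} outside [0, 100]")
        # total_sugars is a subset of digestible carbohydrates: excluded.
        closure = (
            self.protein + self.fat_total + self.digestible_carbohydrates
            + self.dietary_fiber + self.ash
        )
        if closure > 100 + self.MASS_TOLERANCE:
            raise ValidationError(
                f"component sum {closure:.2f} exceeds 100 %"
            )


@dataclass
class ReferencePattern:
    """Essential amino-acid requirement pattern in g/100 g protein.

    ``composites`` maps pooled keys such as ``"Met+Cys"`` to the single codes
    they sum; composite keys must not shadow singles within one pattern.
    """

    name: str
    requirements: dict[str, float]
    composites: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.requirements:
            raise ValidationError(f"{self.name}: empty requirement pattern")
        for group, req in self.requirements.items():
            if not (req > 0 and math.isfinite(req)):
                raise ValidationError(
                    f"{self.name}: requirement for {group} must be > 0"
                )
        for comp, members in self.composites.items():
            for m in members:
                if m in self.requirements:
                    raise ValidationError(
                        f"{self.name}: composite {comp} overlaps single key {m}"
                    )


# Requirement patterns shipped with the package: the Institute of Medicine
# theoretical reference protein for persons >1 year of age, and whole-egg
# protein (FAO/WHO), both in g amino acid / 100 g protein.
_BUILTIN_PATTERNS = {
    "iom": ReferencePattern(
        name="IOM >1 yr",
        requirements={
            "Ile": 2.5, "Leu": 5.5, "Lys": 5.1, "Met+Cys": 2.5,
            "Tyr+Phe": 4.7, "Thr": 2.7, "Trp": 0.7, "Val": 3.2, "His": 1.8,
        },
        composites={"Met+Cys": ["Met", "Cys"], "Tyr+Phe": ["Tyr", "Phe"]},
    ),
    "egg": ReferencePattern(
        name="egg FAO/WHO",
        requirements={
            "Ile": 5.9, "Leu": 8.5, "Lys": 6.3, "Met+Cys": 5.6,
            "Tyr+Phe": 7.0, "Thr": 4.7, "Trp": 1.5, "Val": 6.9, "His": 2.3,
        },
        composites={"Met+Cys": ["Met", "Cys"], "Tyr+Phe": ["Tyr", "Phe"]},
    ),
}


def builtin_pattern(name: str) -> ReferencePattern:
    """Return a shipped reference pattern by short name (``"iom"``, ``"egg"``)."""
    try:
        return _BUILTIN_PATTERNS[name.lower()]
    except KeyError:
        raise KeyError(
            f"no built-in pattern {name!r}; available: "
            f"{sorted(_BUILTIN_PATTERNS)}"
        ) from None
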