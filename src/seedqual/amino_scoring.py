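"""Amino-acid scoring against essential amino-acid reference patterns.

Contents measured per 100 g seed dry matter are first converted to a
per-protein basis (g/100 g protein) by dividing by the crude-protein content;
each pattern group is then scored as

    AAS = (g AA / 100 g test protein) / (g AA / 100 g pattern) x 100 %

and the group with the lowest score is the limiting amino acid.

Composite groups (Met+Cys, Tyr+Phe) sum their member acids at full precision
before any rounding.  For table-style reporting the per-protein values are
rounded half-up to 2 decimals *before* scoring, which is the convention of
published composition tables (the printed score columns are reproducible only
from the rounded per-protein columns); the raw score path is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._round import round_half_up
from .model import AminoAcidProfile, ReferencePattern, ValidationError

__all__ = ["AASResult", "to_per_protein", "amino_acid_score", "score_profile"]


@dataclass
class AASResult:
    """Scores of one profile against one pattern.

    ``per_protein`` holds the values actually scored (g/100 g protein,
    composites included); ``scores`` maps each pattern group to its AAS in %;
    ``missing`` lists pattern groups with no matching data, which are excluded
    from the limiting determination.
    """

    pattern_name: str
    per_protein: dict[str, float]
    scores: dict[str, float]
    limiting: str | None
    missing: list[str] = field(default_factory=list)


def to_per_protein(profile: AminoAcidProfile) -> dict[str, float]:
    """Convert contents from g/100 g DM to g/100 g protein (raw doubles)."""
    if not profile.protein_pct_dm or profile.protein_pct_dm <= 0:
        raise ValidationError(
            f"{profile.sample_id}: protein_pct_dm must be > 0 for conversion"
        )
    return {
        code: value / profile.protein_pct_dm * 100.0
        for code, value in profile.contents_dm.items()
    }


def _resolve_group(
    group: str, per_protein: dict[str, float], pattern: ReferencePattern
) -> float | None:
    """Per-protein value for a pattern group; None when no data matches."""
    if group in per_protein:
        return per_protein[group]
    members = pattern.composites.get(group)
    if members is None:
        # Tolerate an unordered composite spelling such as "Phe+Tyr".
        parts = [p.strip() for p in group.split("+")]
        if len(parts) > 1 and all(p in per_protein for p in parts):
            return sum(per_protein[p] for p in parts)
        return None
    if not all(m in per_protein for m in members):
        return None
    return sum(per_protein[m] for m in members)


def amino_acid_score(
    per_protein: dict[str, float],
    pattern: ReferencePattern,
    round_inputs: int | None = None,
) -> AASResult:
    """Score a per-protein amino-acid map against a reference pattern.

    ``round_inputs`` optionally rounds each resolved per-protein value
    (half-up, that many decimals) before dividing by the requirement — the
    table-reporting convention.  Scores are returned raw; round for display.
    The limiting group is the argmin of the scores; ties are broken
    alphabetically with a warning.
    """
    scored: dict[str, float] = {}
    resolved: dict[str, float] = {}
    missing: list[str] = []
    for group, requirement in pattern.requirements.items():
        value = _resolve_group(group, per_protein, pattern)
        if value is None:
            missing.append(group)
            continue
        if round_inputs is not None:
            value = round_half_up(value, round_inputs)
        resolved[group] = value
        scored[group] = value / requirement * 100.0
    limiting = None
    if scored:
        lowest = min(scored.values())
        ties = sorted(g for g, s in scored.items() if s == lowest)
        if len(ties) > 1:
            warnings.warn(
                f"limiting amino acid tie between {ties}; "
                "reporting the alphabetically first",
                stacklevel=2,
            )
        limiting = ties[0]
    return AASResult(
        pattern_name=pattern.name,
        per_protein=resolved,
        scores=scored,
        limiting=limiting,
        missing=missing,
    )


def score_profile(
    profile: AminoAcidProfile,
    pattern: ReferencePattern,
    report_rounding: int | None = 2,
) -> AASResult:
    """Full pipeline: DM contents -> per-protein -> AAS.

    With the default ``report_rounding=2`` the per-protein values are rounded
    to 2 decimals before scoring (matching printed composition tables); pass
    ``None`` for the raw double-precision path.
    """
    return amino_acid_score(
        to_per_protein(profile), pattern, round_inputs=report_rounding
    )
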