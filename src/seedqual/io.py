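"""Readers and writers for the CSV/JSON interchange formats.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator.  Fatty-acid and amino-acid profiles are one sample per file unless
a ``sample_id`` column is present.  Reference patterns travel as JSON::

    {"name": ..., "requirements": {...},
     "composites": {"Met+Cys": ["Met", "Cys"], "Tyr+Phe": ["Tyr", "Phe"]}}
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import (
    AminoAcidProfile,
    FattyAcidProfile,
    FattyAcidRecord,
    ProximateComposition,
    ReferencePattern,
    ValidationError,
    format_fa_notation,
    parse_fa_notation,
)

__all__ = [
    "read_fa_profile",
    "write_fa_profile",
    "read_aa_profile",
    "write_aa_profile",
    "read_proximate",
    "write_proximate",
    "read_pattern",
    "write_pattern",
]

_FA_REQUIRED = ("common_name", "notation", "pct_total_fa")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValidationError(f"{path}: no records")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    try:
        return pd.to_numeric(df[col])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric value in column {col!r}: {exc}")


def read_fa_profile(path, sample_id: str | None = None) -> FattyAcidProfile:
    """Load a fatty-acid profile CSV.

    Required columns: ``common_name``, ``notation``, ``pct_total_fa``;
    optional: ``g_per_100g_dm``, ``total_fat_pct_dm``, ``sample_id``.
    Rows are preserved in input order; a duplicated acid is an error.
    """
    df = _read_csv(path)
    missing = [c for c in _FA_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if sample_id is None:
        if "sample_id" in df.columns:
            ids = df["sample_id"].unique()
            if len(ids) > 1:
                raise ValidationError(
                    f"{path}: multiple sample_ids {list(ids)}; pass sample_id="
                )
            sample_id = str(ids[0])
        else:
            sample_id = Path(str(path)).stem
    elif "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
        if df.empty:
            raise ValidationError(f"{path}: no rows for sample {sample_id!r}")

    pct = _numeric(df, "pct_total_fa", path)
    g_dm = (
        _numeric(df, "g_per_100g_dm", path)
        if "g_per_100g_dm" in df.columns
        else pd.Series([None] * len(df), index=df.index)
    )
    records = [
        FattyAcidRecord(
            common_name=str(row.common_name),
            notation=parse_fa_notation(str(row.notation)),
            pct_total_fa=float(p),
            g_per_100g_dm=None if pd.isna(g) else float(g),
        )
        for row, p, g in zip(df.itertuples(), pct, g_dm)
    ]
    total_fat = None
    if "total_fat_pct_dm" in df.columns:
        vals = pd.to_numeric(df["total_fat_pct_dm"]).dropna().unique()
        if len(vals) > 1:
            raise ValidationError(f"{path}: inconsistent total_fat_pct_dm")
        if len(vals) == 1:
            total_fat = float(vals[0])
    return FattyAcidProfile(
        sample_id=sample_id, records=records, total_fat_pct_dm=total_fat
    )


def write_fa_profile(profile: FattyAcidProfile, path) -> None:
    rows = [
        {
            "sample_id": profile.sample_id,
            "common_name": r.common_name,
            "notation": format_fa_notation(r.notation),
            "pct_total_fa": r.pct_total_fa,
            "g_per_100g_dm": r.g_per_100g_dm,
            "total_fat_pct_dm": profile.total_fat_pct_dm,
        }
        for r in profile.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_aa_profile(path, sample_id: str | None = None) -> AminoAcidProfile:
    """Load an amino-acid profile CSV with columns ``code``, ``g_per_100g_dm``
    and optional ``protein_pct_dm`` / ``sample_id``."""
    df = _read_csv(path)
    for col in ("code", "g_per_100g_dm"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if sample_id is None:
        sample_id = (
            str(df["sample_id"].iloc[0])
            if "sample_id" in df.columns
            else Path(str(path)).stem
        )
    elif "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    values = _numeric(df, "g_per_100g_dm", path)
    contents = {}
    for code, v in zip(df["code"], values):
        if code in contents:
            raise ValidationError(f"{path}: duplicate amino acid {code!r}")
        contents[str(code)] = float(v)
    protein = None
    if "protein_pct_dm" in df.columns:
        vals = pd.to_numeric(df["protein_pct_dm"]).dropna().unique()
        if len(vals) > 1:
            raise ValidationError(f"{path}: inconsistent protein_pct_dm")
        if len(vals) == 1:
            protein = float(vals[0])
    return AminoAcidProfile(
        sample_id=sample_id, contents_dm=contents, protein_pct_dm=protein
    )


def write_aa_profile(profile: AminoAcidProfile, path) -> None:
    rows = [
        {
            "sample_id": profile.sample_id,
            "code": code,
            "g_per_100g_dm": v,
            "protein_pct_dm": profile.protein_pct_dm,
        }
        for code, v in profile.contents_dm.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_proximate(path, sample_id: str | None = None) -> ProximateComposition:
    """Load a proximate-composition CSV (long format: ``component``, ``value``)."""
    df = _read_csv(path)
    for col in ("component", "value"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if sample_id is None:
        sample_id = (
            str(df["sample_id"].iloc[0])
            if "sample_id" in df.columns
            else Path(str(path)).stem
        )
    elif "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    values = _numeric(df, "value", path)
    known = set(ProximateComposition._COMPONENTS) | {"dry_matter_pct"}
    kwargs: dict[str, float] = {}
    for comp, v in zip(df["component"], values):
        comp = str(comp)
        if comp not in known:
            raise ValidationError(f"{path}: unknown component {comp!r}")
        kwargs[comp] = float(v)
    return ProximateComposition(sample_id=sample_id, **kwargs)


def write_proximate(comp: ProximateComposition, path) -> None:
    rows = [
        {"sample_id": comp.sample_id, "component": name, "value": getattr(comp, name)}
        for name in comp._COMPONENTS
    ]
    if comp.dry_matter_pct is not None:
        rows.append(
            {
                "sample_id": comp.sample_id,
                "component": "dry_matter_pct",
                "value": comp.dry_matter_pct,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_pattern(path) -> ReferencePattern:
    """Load a reference pattern from JSON."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        return ReferencePattern(
            name=data["name"],
            requirements={k: float(v) for k, v in data["requirements"].items()},
            composites={k: list(v) for k, v in data.get("composites", {}).items()},
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing pattern field {exc}")


def write_pattern(pattern: ReferencePattern, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "name": pattern.name,
                "requirements": pattern.requirements,
                "composites": pattern.composites,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
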