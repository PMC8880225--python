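"""Reference tables, deterministic fixtures and random test profiles.

Everything any analysis stage needs is derivable offline from the constants
embedded here: the published composition tables of the two hemp varieties
('Bialobrzeskie' and 'Henola', n = 3 replicates reported as mean ± SD),
exact-moment replicate triplets reconstructed from those summaries, and
seeded random fatty-acid profiles for property testing.

A few printed cells are carried verbatim but flagged as discrepant where the
stated formulas do not reproduce them (see :data:`DISCREPANT_CELLS`); golden
tests assert "matches within documented tolerance OR flagged".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as sio
from .model import (
    AminoAcidProfile,
    FattyAcidProfile,
    FattyAcidRecord,
    ProximateComposition,
    ValidationError,
    builtin_pattern,
    parse_fa_notation,
)

__all__ = [
    "VARIETIES",
    "PROXIMATE_TABLE",
    "FA_TABLE",
    "LIPID_INDEX_TABLE",
    "AA_TABLE",
    "AA_COMPOSITE_TABLE",
    "AAS_TABLE",
    "DISCREPANT_CELLS",
    "fa_profile",
    "aa_profile",
    "proximate",
    "grouped_rows",
    "replicate_triplets",
    "RandomProfileSpec",
    "random_profile",
    "FixtureSet",
    "make_fixtures",
]

VARIETIES = ("Bialobrzeskie", "Henola")

# Proximate composition and energy: parameter -> (unit, (mean, sd, letter)
# per variety).  Starred components are on the dry-matter basis.
PROXIMATE_TABLE: dict[str, tuple[str, tuple, tuple]] = {
    "energy_kj": ("kJ/100 g", (1860.0, 18.83, "a"), (1905.0, 11.31, "a")),
    "energy_kcal": ("kcal/100 g", (451.0, 4.46, "a"), (461.0, 2.74, "a")),
    "dry_matter_pct": ("%", (91.38, 2.25, "a"), (92.44, 0.64, "a")),
    "protein": ("%", (23.54, 0.59, "a"), (23.39, 0.38, "a")),
    "total_sugars": ("%", (2.01, 0.11, "a"), (2.09, 0.01, "a")),
    "digestible_carbohydrates": ("%", (2.02, 0.24, "a"), (4.48, 0.25, "b")),
    "dietary_fiber": ("%", (28.88, 0.18, "a"), (27.42, 0.34, "b")),
    "fat_total": ("%", (32.28, 0.41, "a"), (32.75, 1.70, "a")),
    "sfa_g_per_100g": ("g/100 g", (3.48, 0.40, "a"), (3.98, 0.25, "a")),
    "ash": ("%", (4.66, 0.47, "a"), (4.40, 0.16, "a")),
}

# Fatty-acid profile: common name -> (notation, (mean, sd, letter) per
# variety in % of total FA, then the printed g/100 g DM pair).
FA_TABLE: dict[str, tuple[str, tuple, tuple, float, float]] = {
    "palmitic": ("C16:0", (6.75, 0.71, "a"), (7.76, 0.89, "a"), 2.18, 2.54),
    "palmitoleic": ("C16:1 n-7", (0.16, 0.05, "a"), (0.16, 0.02, "a"), 0.05, 0.05),
    "margaric": ("C17:0", (0.07, 0.00, "a"), (0.06, 0.00, "a"), 0.02, 0.02),
    "stearic": ("C18:0", (2.65, 0.08, "a"), (2.84, 0.11, "a"), 0.86, 0.93),
    "oleic": ("C18:1 n-9", (12.28, 1.75, "a"), (11.95, 1.37, "a"), 3.96, 3.91),
    "cis-vaccenic": (
        "C18:1 n-7 (11 cis)", (0.96, 0.07, "a"), (0.96, 0.09, "a"), 0.31, 0.31,
    ),
    "linoleic": ("C18:2 n-6", (56.46, 2.40, "a"), (53.35, 3.01, "a"), 18.22, 17.48),
    "gamma-linolenic": ("C18:3 n-6", (3.33, 0.41, "a"), (1.56, 0.13, "b"), 1.07, 0.51),
    "alpha-linolenic": ("C18:3 n-3", (14.60, 1.85, "a"), (19.15, 2.06, "a"), 4.71, 6.27),
    "stearidonic": ("C18:4 n-3", (0.87, 0.11, "a"), (0.00, 0.00, "b"), 0.28, 0.00),
    "arachidic": ("C20:0", (0.77, 0.09, "a"), (0.86, 0.11, "a"), 0.25, 0.28),
    "cis-11-eicosenoic": ("C20:1", (0.34, 0.06, "a"), (0.43, 0.04, "a"), 0.11, 0.14),
    "eicosadienoic": ("C20:2", (0.06, 0.01, "a"), (0.06, 0.00, "a"), 0.02, 0.02),
    "behenic": ("C22:0", (0.31, 0.05, "a"), (0.34, 0.06, "a"), 0.10, 0.11),
    "erucic": ("C22:1 n-9", (0.00, 0.00, "b"), (0.07, 0.00, "a"), 0.00, 0.02),
    "lignoceric": ("C24:0", (0.14, 0.00, "a"), (0.17, 0.00, "b"), 0.05, 0.06),
    "nervonic": ("C24:1 n-9", (0.00, 0.00, "b"), (0.07, 0.01, "a"), 0.00, 0.02),
}

# Published lipid health indicators: index -> (mean, sd, letter) per variety.
LIPID_INDEX_TABLE: dict[str, tuple[tuple, tuple]] = {
    "n6_n3_ratio": ((3.86, 0.33, "a"), (2.87, 0.61, "a")),
    "pufa_sfa_ratio": ((7.06, 1.03, "a"), (6.17, 0.73, "a")),
    "ai": ((0.08, 0.01, "a"), (0.09, 0.01, "a")),
    "ti": ((0.03, 0.00, "a"), (0.03, 0.00, "a")),
    "h_to_h": ((12.98, 3.00, "a"), (11.21, 1.82, "a")),
}

# Amino acids: code -> ((content mean, sd), per-protein) per variety.
# Contents in g/100 g DM; per-protein in g/100 g protein as printed.
AA_TABLE: dict[str, tuple[tuple, float, tuple, float]] = {
    "Lys": ((0.754, 0.098), 3.20, (0.752, 0.098), 3.22),
    "Met": ((0.497, 0.065), 2.11, (0.463, 0.060), 1.98),
    "Cys": ((0.330, 0.060), 1.40, (0.320, 0.060), 1.37),
    "Asp": ((2.160, 0.280), 9.18, (2.020, 0.260), 8.64),
    "Thr": ((0.718, 0.093), 3.05, (0.648, 0.084), 2.77),
    "Ser": ((0.990, 0.130), 4.21, (0.920, 0.120), 3.93),
    "Glu": ((3.590, 0.390), 15.25, (3.410, 0.380), 14.58),
    "Pro": ((0.820, 0.110), 3.48, (0.810, 0.110), 3.46),
    "Gly": ((0.930, 0.120), 3.95, (0.880, 0.110), 3.76),
    "Ala": ((0.900, 0.120), 3.82, (0.860, 0.110), 3.68),
    "Val": ((0.970, 0.130), 4.12, (0.980, 0.130), 4.19),
    "Ile": ((0.830, 0.110), 3.53, (0.800, 0.100), 3.42),
    "Leu": ((1.310, 0.170), 5.56, (1.290, 0.170), 5.52),
    "Tyr": ((0.571, 0.074), 2.43, (0.523, 0.068), 2.24),
    "Phe": ((0.890, 0.120), 3.78, (0.930, 0.120), 3.98),
    "His": ((0.565, 0.073), 2.40, (0.527, 0.068), 2.25),
    "Arg": ((2.480, 0.320), 10.54, (2.260, 0.290), 9.66),
    "Trp": ((0.437, 0.060), 1.86, (0.322, 0.065), 1.38),
}

# Composite rows as printed: key -> (content, per-protein) per variety.
AA_COMPOSITE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "Met+Cys": (0.827, 3.51, 0.783, 3.35),
    "Tyr+Phe": (1.461, 6.21, 1.453, 6.21),
}

# Published amino acid scores (%, IOM pattern): group -> per-variety value.
AAS_TABLE: dict[str, tuple[float, float]] = {
    "Ile": (141.20, 136.80),
    "Leu": (101.09, 100.36),
    "Lys": (62.75, 63.14),
    "Met+Cys": (140.40, 134.00),
    "Tyr+Phe": (132.13, 132.13),
    "Thr": (112.76, 102.59),
    "Trp": (265.71, 197.14),
    "Val": (128.75, 130.94),
    "His": (133.33, 125.00),
}

#: Printed cells the stated formulas do not reproduce, carried verbatim:
#: (table, row, variety) -> note.
DISCREPANT_CELLS: dict[tuple[str, str, str], str] = {
    ("lipid_indices", "ti", "Bialobrzeskie"):
        "printed 0.03; the stated TI formula on the printed percentage "
        "column gives ~0.113",
    ("lipid_indices", "ti", "Henola"):
        "printed 0.03; the stated TI formula gives ~0.115",
    ("aas", "Thr", "Bialobrzeskie"):
        "printed 112.76; 3.05/2.7*100 = 112.96 (Henola's cell is exact)",
    ("fa_g_dm", "linoleic", "Bialobrzeskie"):
        "printed 18.22; 56.46*32.28/100 = 18.2253 rounds to 18.23",
}


def proximate(variety: str) -> ProximateComposition:
    """Proximate composition of one variety (dry-matter basis)."""
    col = VARIETIES.index(variety)
    get = lambda key: PROXIMATE_TABLE[key][1 + col][0]
    return ProximateComposition(
        sample_id=variety,
        protein=get("protein"),
        digestible_carbohydrates=get("digestible_carbohydrates"),
        total_sugars=get("total_sugars"),
        dietary_fiber=get("dietary_fiber"),
        fat_total=get("fat_total"),
        ash=get("ash"),
        dry_matter_pct=get("dry_matter_pct"),
    )


def fa_profile(variety: str, with_g_dm: bool = True) -> FattyAcidProfile:
    """Fatty-acid profile of one variety, including the total-fat context."""
    col = VARIETIES.index(variety)
    records = [
        FattyAcidRecord(
            common_name=name,
            notation=parse_fa_notation(row[0]),
            pct_total_fa=row[1 + col][0],
            g_per_100g_dm=row[3 + col] if with_g_dm else None,
        )
        for name, row in FA_TABLE.items()
    ]
    return FattyAcidProfile(
        sample_id=variety,
        records=records,
        total_fat_pct_dm=PROXIMATE_TABLE["fat_total"][1 + col][0],
    )


def aa_profile(variety: str) -> AminoAcidProfile:
    """Amino-acid profile (single acids; composites derive from them)."""
    col = 0 if variety == VARIETIES[0] else 2
    return AminoAcidProfile(
        sample_id=variety,
        contents_dm={code: row[col][0] for code, row in AA_TABLE.items()},
        protein_pct_dm=PROXIMATE_TABLE["protein"][1 + VARIETIES.index(variety)][0],
    )


def grouped_rows(tables: tuple[str, ...] = ("proximate", "fatty_acids", "lipid_indices")):
    """Yield (table, analyte, summary, printed letters) for every mean±SD row.

    ``summary`` maps variety -> (mean, sd); ``letters`` maps variety -> the
    printed superscript.  Feed the summaries through exact-moment triplets to
    recompute the letters.
    """
    sources = {
        "proximate": {k: (v[1], v[2]) for k, v in PROXIMATE_TABLE.items()},
        "fatty_acids": {k: (v[1], v[2]) for k, v in FA_TABLE.items()},
        "lipid_indices": {k: (v[0], v[1]) for k, v in LIPID_INDEX_TABLE.items()},
    }
    for table in tables:
        for analyte, (b, h) in sources[table].items():
            summary = {
                VARIETIES[0]: (b[0], b[1]),
                VARIETIES[1]: (h[0], h[1]),
            }
            letters = {VARIETIES[0]: b[2], VARIETIES[1]: h[2]}
            yield table, analyte, summary, letters


def replicate_triplets(
    mean: float, sd: float, n: int = 3, seed: int | None = None
) -> list[float]:
    """Reconstruct replicates from a published (mean, SD) summary.

    For n = 3 the exact construction {m - s, m, m + s} is used: its sample
    mean and sample SD (ddof = 1) equal (m, s) exactly.  Other n require a
    seed; a Gaussian draw is then affinely standardised to the exact moments.
    """
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if n == 3:
        return [mean - sd, mean, mean + sd]
    if seed is None:
        raise ValidationError("n != 3 requires a seed (Gaussian sampling)")
    if n < 2:
        raise ValidationError("need n >= 2 replicates")
    if sd == 0:
        return [mean] * n
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    while np.std(z, ddof=1) == 0:  # pragma: no cover - measure-zero event
        z = rng.standard_normal(n)
    z = (z - z.mean()) / np.std(z, ddof=1)
    return list(mean + sd * z)


# Candidate pool for random profiles: plausible seed-oil acids.
_RANDOM_POOL = (
    "C12:0", "C14:0", "C17:0", "C18:0", "C20:0", "C22:0", "C24:0",
    "C16:1 n-7", "C18:1 n-9", "C18:1 n-7", "C20:1", "C22:1 n-9", "C24:1 n-9",
    "C18:3 n-6", "C18:4 n-3", "C20:2", "C20:3 n-6", "C20:4 n-6",
    "C20:5 n-3", "C22:4 n-6", "C22:5 n-3", "C22:6 n-3",
)
#: Acids every random profile contains so all five indices are defined.
_RANDOM_CORE = ("C16:0", "C18:2 n-6", "C18:3 n-3")


@dataclass(frozen=True)
class RandomProfileSpec:
    """Specification for a seeded random fatty-acid profile.

    Shares are Dirichlet-distributed over the selected acids (symmetric
    concentration ``concentration``) and scaled to sum to exactly 100.
    """

    n_acids: int = 10
    seed: int = 0
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.n_acids < 3:
            raise ValidationError("n_acids must be >= 3")
        if self.n_acids > len(_RANDOM_POOL) + len(_RANDOM_CORE):
            raise ValidationError("n_acids exceeds the candidate pool")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")


def random_profile(spec: RandomProfileSpec) -> FattyAcidProfile:
    """Seeded random profile; always contains C16:0 and one n-3/n-6 acid."""
    rng = np.random.default_rng(spec.seed)
    extra = spec.n_acids - len(_RANDOM_CORE)
    chosen = list(_RANDOM_CORE) + list(
        rng.choice(_RANDOM_POOL, size=extra, replace=False)
    )
    shares = rng.dirichlet(np.full(len(chosen), spec.concentration)) * 100.0
    shares[-1] = 100.0 - shares[:-1].sum()  # force exact closure
    records = [
        FattyAcidRecord(
            common_name=key, notation=parse_fa_notation(key), pct_total_fa=float(s)
        )
        for key, s in zip(chosen, shares)
    ]
    return FattyAcidProfile(
        sample_id=f"random-{spec.seed}",
        records=records,
        total_fat_pct_dm=float(rng.uniform(10.0, 50.0)),
    )


@dataclass
class FixtureSet:
    """Paths of the generated fixture files."""

    root: Path
    proximate: dict[str, Path]
    fa_profiles: dict[str, Path]
    aa_profiles: dict[str, Path]
    patterns: dict[str, Path]
    lipid_index_expected: Path
    aas_expected: Path
    manifest: Path


def make_fixtures(out_dir) -> FixtureSet:
    """Write the full fixture set to ``out_dir`` (deterministic bytes)."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    proximate_paths, fa_paths, aa_paths = {}, {}, {}
    manifest: dict[str, str] = {}
    for variety in VARIETIES:
        p = root / f"proximate_{variety.lower()}.csv"
        sio.write_proximate(proximate(variety), p)
        proximate_paths[variety] = p
        manifest[p.name] = "proximate composition and energy table"

        p = root / f"fa_profile_{variety.lower()}.csv"
        sio.write_fa_profile(fa_profile(variety), p)
        fa_paths[variety] = p
        manifest[p.name] = "fatty-acid profile table (% of total FA and g/100 g DM)"

        p = root / f"aa_profile_{variety.lower()}.csv"
        sio.write_aa_profile(aa_profile(variety), p)
        aa_paths[variety] = p
        manifest[p.name] = "amino-acid content table (g/100 g DM)"

    pattern_paths = {}
    for name in ("iom", "egg"):
        p = root / f"pattern_{name}.json"
        sio.write_pattern(builtin_pattern(name), p)
        pattern_paths[name] = p
        manifest[p.name] = "essential amino-acid requirement pattern"

    import pandas as pd

    idx_path = root / "lipid_indices_expected.csv"
    pd.DataFrame(
        [
            {
                "index": key,
                "variety": variety,
                "mean": row[i][0],
                "sd": row[i][1],
                "letter": row[i][2],
                "discrepant": ("lipid_indices", key, variety) in DISCREPANT_CELLS,
            }
            for key, row in LIPID_INDEX_TABLE.items()
            for i, variety in enumerate(VARIETIES)
        ]
    ).to_csv(idx_path, index=False)
    manifest[idx_path.name] = "published lipid health indicators"

    aas_path = root / "aas_expected.csv"
    pd.DataFrame(
        [
            {
                "group": group,
                "variety": variety,
                "aas": values[i],
                "discrepant": ("aas", group, variety) in DISCREPANT_CELLS,
            }
            for group, values in AAS_TABLE.items()
            for i, variety in enumerate(VARIETIES)
        ]
    ).to_csv(aas_path, index=False)
    manifest[aas_path.name] = "published amino acid scores (IOM pattern)"

    manifest_path = root / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixtureSet(
        root=root,
        proximate=proximate_paths,
        fa_profiles=fa_paths,
        aa_profiles=aa_paths,
        patterns=pattern_paths,
        lipid_index_expected=idx_path,
        aas_expected=aas_path,
        manifest=manifest_path,
    )
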