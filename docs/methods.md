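# Methods

`seedqual` reproduces, from published summary tables alone, the complete
computational layer of a seed-composition study of two industrial hemp
(*Cannabis sativa* L.) varieties, 'Bialobrzeskie' and 'Henola': fatty-acid
classification and basis conversion, lipid nutritional-quality indices,
amino-acid scoring, EU-label energy values, and the ANOVA + Duncan letter
displays that annotate the tables.

## Fatty-acid model

An acid is identified by its shorthand notation `C<carbons>:<double bonds>`
with an optional omega-family token (`n-3`, `n-6`, `n-7`, `n-9`). The parser
accepts the typographic dialects of journal tables — `n − 3` with a unicode
minus, `n-3`, `ω-3` — and canonicalises to `n-3`. Acids printed without a
family token (C20:1, C20:2) keep `family = unspecified`: they count toward
their unsaturation class but never toward an n-3/n-6 family sum unless the
caller supplies an explicit override map, because silently guessing a family
would change the family-sum indices.

Classification is a pure function of the double-bond count (0 → SFA,
1 → MUFA, ≥2 → PUFA, subdivided di/tri/tetra/…). Class shares are summed
over records *as given*, never renormalised to 100: published profiles sum
to ≈99.8 % after per-row rounding, and renormalising would shift every
index away from the printed values.

The two abundance bases are linked by the total-fat content of the seed:
`g/100 g DM = (% of total FA) × (fat % DM) / 100`. Recomputing every
published mass cell this way agrees within ±0.015 g/100 g DM, the
worst cell being linoleic acid (print-rounding of the inputs explains the
residue).

## Lipid quality indices

All five indices are computed on the %-of-total-FA basis, the only reading
that reproduces the printed AI and h/H:

* `PUFA/SFA = (ΣDiUFA + ΣTriUFA + ΣTetraUFA + higher)/ΣSFA`
* `n-6/n-3 = (C18:2 n-6 + C18:3 n-6)/(C18:3 n-3 + C18:4 n-3)` — the
  four-acid enumeration that dominates seed oils; a family-sum variant
  (`Σn-6/Σn-3`) is available behind a flag.
* `AI = (C12:0 + 4·C14:0 + C16:0)/ΣUFA`
* `TI = (C14:0 + C16:0 + C18:0)/(0.5·MUFA + 0.5·Σn-6 + 3·Σn-3 + Σn-3/Σn-6)`
* `h/H =` eleven hypocholesterolemic unsaturated acids over `(C14:0 + C16:0)`

Acids absent from a profile contribute zero (the published profiles lack
C12:0 and C14:0 entirely); a zero denominator raises an error rather than
returning infinity. Raw doubles are kept internally; table reports round
half-up to 2 decimals (`decimal`-based, since Python's built-in `round` is
banker's rounding).

Known discrepancy: with the percentage column as input, the TI formula
yields 0.113 ('Bialobrzeskie') and 0.115 ('Henola'), not the published 0.03.
No self-consistent basis choice reproduces 0.03 (a mixed numerator in
g/100 g DM gets only as close as ≈0.04). The implementation follows the
formula; the fixture stores the published cell verbatim with a `discrepant`
flag, and the analysis stage reports the disagreement.

All indices are ratios of degree-1 sums and therefore invariant under
uniform rescaling of abundances — except TI, whose `Σn-3/Σn-6` term is
already degree-0, making TI scale-invariant only on proper %-share inputs.
A further caveat the property suite encodes: TI is *not* monotone under an
arbitrary single-acid UFA increase, because inflating an n-6 acid can shrink
the `Σn-3/Σn-6` term faster than the weighted sums grow; under proportional
scaling of all unsaturated acids (which fixes that term) both AI and TI
strictly decrease, and AI is monotone under any single-UFA increase.

## Amino-acid scoring

Contents are measured in g/100 g dry matter; dividing by the crude-protein
content (% DM, an N×6.25 value taken as input) and multiplying by 100 gives
g/100 g protein. Composite groups (Met+Cys, Tyr+Phe) are summed at full
precision before rounding. Cys and Met are accepted under their analytical
aliases "cysteic acid" and "methionine sulphone".

Scores against a requirement pattern are
`AAS = per-protein / requirement × 100 %`; the minimum over scored groups is
the limiting amino acid (Lys for both varieties, AAS 62.75 / 63.14 %). Two
patterns ship built in: the IOM theoretical reference protein for persons
older than one year, and whole-egg protein (FAO/WHO), both in g/100 g
protein.

Reporting convention: the published score table is reproducible only when
scores are computed from the per-protein values *rounded to 2 decimals*
(e.g. Lys 3.20/5.1×100 = 62.75 as printed; the unrounded 3.2031 would give
62.81), with composites rounded from the unrounded sum. `score_profile`
therefore rounds per-protein values half-up to 2 decimals by default and
exposes the raw path via `report_rounding=None`. One published cell
(Thr, 'Bialobrzeskie', 112.76) differs from its own inputs
(3.05/2.7×100 = 112.96) and is carried with a `discrepant` flag; the
'Henola' Thr cell is exact.

## Energy values

`kJ = 17·protein + 17·digestible carbohydrates + 37·fat + 8·fibre` and the
kcal analogue with (4, 4, 9, 2), per Regulation (EU) No 1169/2011. Total
sugars are a subset of digestible carbohydrate and are never added
separately. The factor pairs are regulatory constants, not 4.184
conversions of each other. The computation is basis-agnostic: the published
energy rows are reproduced exactly (1859.9 → 1860 and 1904.9 → 1905 kJ;
450.5 → 451 and 461.1 → 461 kcal) when the dry-matter-basis components are
used directly, so the module computes on whatever basis the input declares
and leaves moisture re-basing to the caller.

## Group comparison

Replicate values per (analyte × group) go through a standard one-way ANOVA;
Duncan's multiple range test then compares ranked means against the least
significant range `R_p = q(α_p, p, df) · √(MSE/n)` with protection level
`α_p = 1 − (1−α)^(p−1)` for a span of `p` means (studentized-range quantiles
from `scipy.stats.studentized_range`). Maximal non-significant stretches of
the ranked means become the compact letters. With two groups the procedure
reduces to a protected LSD, so the letter verdict equals the ANOVA `p < α`
decision; the tests verify both this reduction and agreement with an
independent pooled t-test oracle.

Conventions for degenerate data: zero within-group variance gives `p = 1`
(equal means) or `p = 0` (unequal); a group that is identically zero — a
below-detection analyte such as erucic acid in 'Bialobrzeskie' — is excluded
from the error-variance pooling, with a note; unequal group sizes use the
harmonic-mean n, with a warning.

Letter naming follows the published tables' convention: the homogeneous-group
*partition* is computed on descending means and is invariant to input order,
but letter *names* anchor to the first-listed group, with all-zero groups
named last. This is what the published tables do (digestible carbohydrates:
2.02 "a" vs the larger 4.48 "b"; erucic: 0.00 "b" vs 0.07 "a") and it
reconciles all seven rows with significant differences.

Because raw replicates are unpublished, replicate data are reconstructed
from each printed mean ± SD (n = 3) as the exact-moment triplet
{m−s, m, m+s}, whose sample mean and sample SD equal (m, s) exactly, making
every letter recomputation deterministic. Under this reconstruction 28 of
the 32 table rows reproduce the published superscripts. Four do not, and
the package reports rather than reproduces them:

* both energy rows (kJ: 1860±18.83 vs 1905±11.31, t = 3.55 on 4 df,
  p = 0.024; kcal: p = 0.030) — significantly different by the printed
  summaries, published as not different;
* margaric acid (0.07±0.00 vs 0.06±0.00) — unequal means with zero printed
  variance force significance, published as not different (the true SDs
  presumably round to 0.00 but are nonzero);
* α-linolenic acid (14.60±1.85 vs 19.15±2.06, p = 0.047) — marginally
  significant from the printed summaries, published as not different.

These rows would reconcile if the printed ± values were standard errors
rather than SDs (except margaric), but the source tables state mean ± SD,
so that reading is kept and the disagreement is left visible in the
acceptance suite and in `results/group_letters.csv`.

## Synthetic data

The embedded constants are the published tables themselves; fixture
generation is deterministic (byte-identical on regeneration) and every
flagged cell carries its note. Random fatty-acid profiles for property
testing draw shares from a symmetric Dirichlet over a pool of plausible
seed-oil acids (always including C16:0, one n-3 and one n-6 acid so every
index is defined), scaled to sum to exactly 100; a seed fully determines the
profile. The exact-moment triplets emulate only the first two sample
moments — they say nothing about the distributional shape, outliers or
heteroscedasticity of real chromatographic replicates, so passing letter
recomputations validate the test procedure on the published summaries, not
the underlying raw data.

## Problem sizes

Everything here is desk-scale: 17 fatty acids, 18 amino acids, 2 varieties
× 3 replicates, 32 table rows. The property suites use 100 seeded random
profiles (1000 random summaries for the triplet-moment check); the full test
suite runs in well under a minute on one CPU.
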