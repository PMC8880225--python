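# seedqual

Nutritional-quality informatics for seed composition data. Given the
standard outputs of a food-composition laboratory — a fatty-acid profile
(% of total FA), amino-acid contents (g/100 g dry matter), and a proximate
panel (% DM) — `seedqual` computes the quantities a food scientist reports:

* **fatty-acid classes and bases** — SFA/MUFA/PUFA and omega-family sums,
  and conversion between % of total FA and g/100 g DM via the total-fat
  content;
* **lipid health indices** — PUFA/SFA, n−6/n−3, the atherogenicity index
  AI = (C12:0 + 4·C14:0 + C16:0)/ΣUFA, the thrombogenicity index
  TI = (C14:0 + C16:0 + C18:0)/(0.5·MUFA + 0.5·Σn−6 + 3·Σn−3 + Σn−3/Σn−6),
  and the hypo/hypercholesterolemic ratio h/H;
* **amino acid scores** — AAS = (g AA/100 g test protein)/(g AA/100 g
  pattern) × 100 % against built-in IOM (>1 yr) and egg (FAO/WHO)
  requirement patterns, with the limiting amino acid;
* **label energy values** — kJ and kcal per 100 g under the Regulation (EU)
  No 1169/2011 factors (17/17/37/8 kJ·g⁻¹ for protein/carbohydrate/fat/fibre);
* **significance letters** — one-way ANOVA plus Duncan's multiple range
  test with compact letter display, including exact-moment reconstruction
  of replicates from published mean ± SD summaries.

The package ships the full composition tables of two industrial hemp
varieties ('Bialobrzeskie', 'Henola') as embedded fixtures and, under
`analysis/`, a numbered pipeline that reproduces every published value from
them.

## Worked example

```python
from seedqual import compute_indices, score_profile, energy_report, builtin_pattern
from seedqual import synthetic as syn

profile = syn.fa_profile("Henola")          # 17 acids, % of total FA
print(compute_indices(profile).rounded())
# {'pufa_sfa_ratio': 6.16, 'n6_n3_ratio': 2.87, 'ai': 0.09, 'ti': 0.12, 'h_to_h': 11.21}

aas = score_profile(syn.aa_profile("Henola"), builtin_pattern("iom"))
print(aas.limiting, round(aas.scores[aas.limiting], 2))
# Lys 63.14

print(energy_report(syn.proximate("Henola")))
# (1905, 461)
```

The n−6/n−3 ratio of 2.87 and h/H of 11.21 match the published table for
this variety; AI of 0.09 says atherogenic saturates are under a tenth of
the unsaturated pool; the TI printed in the source table (0.03) is *not*
what its own formula yields (0.12 here) — the package computes the formula
and flags the printed cell as discrepant. Lysine is the limiting amino acid
at 63 % of the IOM requirement, and the proximate panel converts to
1905 kJ / 461 kcal per 100 g dry matter.

The same operations are available from the shell:

```
seedqual indices --input fa_profile.csv
seedqual aas --input aa_profile.csv --pattern iom
seedqual energy --input proximate.csv
seedqual compare --input summaries.csv --from-summary
```

## Analysis pipeline

`analysis/01_build_fixtures.py` … `06_group_letters.py` run the whole
reproduction in order (fixtures → class shares and mass basis → lipid
indices → amino acid scores → energy values → significance letters), each
writing its table under `results/` and printing what it found — including
the rows where the published superscripts cannot be derived from the
published mean ± SD values (see `docs/methods.md`).

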