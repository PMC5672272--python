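# karyotools

Comparative karyotype analysis for plant molecular cytogenetics.

Karyotype studies describe a species' chromosome complement from a handful
of measured metaphase spreads: per-chromosome relative lengths (RL, % of
the haploid complement), arm ratios (AR = long arm / short arm),
centromere-position classes in Levan's nomenclature (m / sm / st / t),
whole-karyotype asymmetry indices, and the positions and sizes of
cytogenetic markers (5S/45S rDNA FISH signals, fluorochrome bands, GISH
blocks). `karyotools` implements that entire desk-side workflow — from raw
per-plate arm-length tables to publication-style SVG idiograms — plus a
companion module for dissecting 5S rDNA repeat-unit amplicons (conserved
120-bp gene + fast-evolving non-transcribed spacer, NTS) and comparing
spacer sequences.

It is aimed at cytogeneticists who have measured chromosomes (e.g. in an
image tool) and want reproducible, scriptable downstream statistics, and at
anyone needing the standard asymmetry indices:

* mean centromeric index CI = 100·s/(s+l), reported mean ± SD over the set
* A1 (intrachromosomal) = 1 − (Σᵢ bᵢ/Bᵢ)/n  — Romero Zarco (1986)
* A2 (interchromosomal) = s/x̄, the CV of chromosome lengths
* As K% = 100 · Σ long arms / Σ total — Arano's long-arm share
* AI = CV(CL) · CV(CI) / 100 — Paszko (2006)
* the Stebbins (1971) two-way category (size ratio × AR > 2 proportion)

All SDs use the sample (n−1) convention; all indices are invariant to
uniform rescaling of the measurements.

## Worked example

The package ships the published karyotype tables of the two cultivated
*Canavalia* species (sword bean *C. gladiata* and jack bean
*C. ensiformis*; 2n = 22, five metaphase plates each) as ready-made
objects:

```python
from karyotools import datasets, asymmetry_profile, marker_summary

kt = datasets.canavalia_gladiata()
print(kt.formula)
# 2n = 22 = 18m + 4m-SAT

print(asymmetry_profile(kt.pairs).to_json())
# {
#   "ci_mean": 42.69840112160058,
#   "ci_sd": 2.8883666212961114,
#   "a1": 0.2507852141001998,
#   "a2": 0.17737270928753385,
#   "ask_percent": 57.04,
#   "ai": 1.1998515156948035,
#   "stebbins": "1A"
# }

totals = marker_summary(kt, datasets.gladiata_marker_sites())["totals"]
print(totals.to_string(index=False))
#  kind  short_total  long_total  total
#   CPD         8.80        8.80  17.60
# sGISH        31.93       29.11  61.04
```

Reading: all 11 pairs are metacentric (AR ≤ 1.70), two pairs carry
satellites, the karyotype is highly symmetric (A1 ≈ 0.25, A2 ≈ 0.18,
Stebbins 1A), sGISH signals cover 61% of the karyotype length and the
centromeric CPD heterochromatin bands about 17.6%.

From the shell, the same pipeline runs on measurement CSVs
(one row per measured homolog):

```sh
karyotools simulate --out demo --seed 1        # synthetic 5-plate fixture
karyotools karyotype --measurements demo/plates.csv --out demo
karyotools asymmetry --measurements demo/plates.csv --out demo
karyotools idiogram  --measurements demo/plates.csv --out demo
karyotools rdna      --fasta demo/amplicons.fasta --out demo
```

## 5S rDNA repeat units

`dissect_amplicon` splits a repeat-unit amplicon into its 40-bp gene tail,
NTS segment(s), optional complete internal 120-bp gene (major amplicons
span two repeat junctions), and 58-bp gene head; `find_promoter` locates
the intragenic A-box / intermediate element / C-box; `global_align`
(affine-gap Needleman–Wunsch) with `count_variable_sites`,
`percent_identity` and `compare_nts_pairs` reproduces the standard
variable-sites / identity / G+C reporting for spacer comparisons.

## Layout

| module | role |
| --- | --- |
| `measurements` | read/validate per-plate arm lengths; aggregate to a karyotype |
| `classification` | Levan centromere classes; karyotype formula strings |
| `asymmetry` | the six-index asymmetry profile |
| `markers` | di positions and band/signal size statistics |
| `idiogram` | deterministic SVG idiograms |
| `rdna_unit` | amplicon dissection, alignment, spacer statistics |
| `synthetic_data` | seeded generators with ground truth for recovery tests |
| `datasets` | the published *Canavalia* tables as fixtures |
| `cli` | `karyotools` command-line entry point |
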