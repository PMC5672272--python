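# Methods

## Measurement model

The unit of observation is one chromosome in one metaphase plate, recorded
as a short-arm and a long-arm length in µm. Orientation on the slide is
arbitrary, so arms are normalised on read (long ≥ short, swapped silently).
By input convention, satellite lengths are included in the arm that carries
them and stretched secondary-constriction lengths are excluded; the reader
stores satellite flags but does no satellite arithmetic.

Within a plate, homologs are averaged to a haploid value per pair; relative
lengths (RL) are each arm's percentage of the plate's haploid complement
length, so the RL totals of a plate sum to 100 exactly. Per-plate AR is the
ratio of homolog-averaged arms, and per-plate CI is 100·s/(s+l). Across
plates, the karyotype table reports the mean and **sample** SD (n−1) of
each per-plate quantity — means of ratios, not ratios of means, matching
how such tables are conventionally printed. Pairs are renumbered 1..n by
decreasing mean RL total (ties broken by input pair id); the original id is
kept in `source_pair_id` so simulation studies can match pairs by identity
rather than rank — two near-equal-sized pairs can legitimately swap rank
under measurement noise.

The total haploid complement length (TCL, µm) is reported over the k most
condensed plates when `condensation_rank` is supplied (condensation varies
chromosome length several-fold across cells, so the convention is to
measure TCL on comparably condensed spreads); without ranks all plates are
used with a warning. The plate sets for per-pair SDs and for TCL are
independent selections, since a measurer may reasonably use different
plates for the two purposes.

## Classification and asymmetry

Levan classes are a pure function of AR: m ≤ 1.70 < sm ≤ 3.00 < st ≤ 7.00
< t. Boundary values belong to the lower class (closed-on-the-left; a
deterministic choice — no real-valued AR estimate sits exactly on a
boundary in practice). The strict "M" point (AR exactly 1) is folded into
m. The karyotype formula counts chromosomes (two per pair), orders types
m, sm, st, t with plain before `-SAT` terms, and omits zero counts.

The six asymmetry indices are computed on the per-pair means of the
aggregated haploid karyotype (one value per species, the standard report),
not per plate. A1 uses 1 − mean(1/AR); A2 is the sample-SD coefficient of
variation of the RL totals; As K% is the long-arm share; AI is the product
of the length CV and the CI CV over 100; CI statistics are across the n
pairs. Sample SDs are used throughout — population SDs visibly change the
second decimal of A2 and AI at n = 11 and do not reproduce conventionally
published values. Stebbins boundaries (size ratio exactly 2; AR exactly 2)
also go to the lower row/column. Note that AI, being a product, vanishes
when *either* CV is zero.

## Markers

A marker site is (pair, kind, arm, d, extent): d is the µm distance from
the centromere to the middle of the site, extent its length along the
chromosome. Derived statistics: di = d·100/a (a = satellite-inclusive arm
length) and size percent = 100·extent/TCL of the same plate. Summaries
accept either µm extents plus per-plate TCLs or pre-derived percents
(published tables print only percents). Centromeric sites have no d; their
extent counts fully toward the pair and complement totals and is split
evenly between arms in the per-arm display columns only. When di values
are derived through the aggregated karyotype, arm length is estimated as
the arm's RL share of the mean TCL.

## Idiograms

SVG 1.1 is the sole output: lossless, diffable, and testable by element
counts. One bar per pair, short arm up, all centromeres on a common
baseline (the conventional alignment); bar heights are RL · scale, so a
size percent and an RL percent share the ordinate. Marker glyphs are
rectangles centred at di-derived offsets with heights equal to their size
percent. Satellites are drawn as a detached block (default 15 % of the
satellite arm) separated by a small gap standing in for the secondary
constriction, whose true length is by convention not part of the
measurements. Floats are serialised at fixed precision, so identical input
produces a byte-identical document.

## 5S repeat units

Dissection fixes the gene flanks at 40 bp (5') and 58 bp (3') — the
primer-anchored gene portions of the amplified repeat — and searches the
interior for a complete 120-bp gene by best ungapped sliding-window match
to a consensus (default threshold 0.70 identity), requiring the AGG…TCC
frame. A confident match ⇒ major amplicon with two NTS segments; no match
⇒ minor amplicon whose whole interior is one NTS, unless the interior
exceeds `max_nts_length` (default 600 bp, comfortably above observed
spacers), which raises. Segment intervals always tile the sequence.

The default gene consensus is a **synthetic** 120-mer constructed to carry
the canonical architecture (AGG start, TCC end, promoter elements at their
canonical offsets: A-box near +50, intermediate element near +67, C-box
near +80); it is a structural stand-in, not a database sequence, and both
the dissector and the simulator accept any user-supplied consensus.
Promoter motifs are found by best ungapped match, searched sequentially so
element order is preserved; a motif below a 0.75 matched-base fraction is
flagged absent rather than raising. The default intermediate-element
consensus is 12 bp: much shorter motifs produce chance matches at this
threshold on random sequence.

The aligner is a Gotoh affine-gap global aligner (a length-L gap costs
`gap_open + (L−1)·gap_extend`), defaults match +1 / mismatch −1 / open −4
/ extend −1 — near classic tool defaults. Tie-breaking is deterministic:
diagonal over up over left. Column statistics trim terminal-gap columns
(primer-anchored amplicons have no meaningful overhangs); an internal gap
column counts as variable and as non-identity, so
identity + 100·variable/columns = 100 by construction, and the aligned
column count can exceed both sequence lengths. Cross-species spacer
comparisons concatenate the 5'NTS-vs-5'NTS and 3'NTS-vs-3'NTS alignments
(counts summed before the identity is formed), since the two spacer
positions are not homologous to each other. GC content excludes IUPAC
ambiguity codes from numerator and denominator.

## Synthetic data

The plate generator's defaults are the study conditions of the shipped
reference karyotype: 11 metacentric pairs with the published RL and AR
vectors, TCL 40.46 µm, five plates, satellites on the short arms of pairs
6 and 7. Each plate draws a condensation factor uniform on [0.85, 1.15]
(so TCL varies across plates as in real spreads); each arm of each homolog
is perturbed by multiplicative lognormal noise with unit mean and CV
0.02 — lognormal keeps lengths positive and mimics condensation
variability, and CV 0.02 yields SD columns of the same order as published
tables. Marker sites are emitted per plate from (pair, kind, arm, di,
size) specs with the same noise on extents.

The amplicon generator assembles major (40 + NTS1 + 120 + NTS2 + 58) and
minor (40 + NTS + 58) amplicons; NTS1 is drawn i.i.d. with a target G+C of
62.9 % (5S spacers in the emulated system are GC-rich), NTS2 derives from
NTS1 by per-site substitutions at the configured divergence (default 0.10)
plus optional length-neutral 1-bp indel churn, then random single-base
indels to reach the configured NTS2 length. All randomness flows from one
seeded NumPy generator; identical configs give byte-identical outputs.

What the generator does **not** emulate: image-level artefacts (overlap,
bending, stretching), correlated measurement error within a plate,
homolog-assignment mistakes, satellite-length variation, gene-region
divergence (transcribed regions are copied exactly), and realistic indel
length distributions. Passing recovery tests therefore demonstrates the
correctness of the statistical pipeline under idealised noise, not
robustness to every failure mode of real slides.

## Numerical choices and limitations

* Sample SD everywhere; single-plate SDs are reported as 0.
* Display rounding is 2 decimals for table export; all internal
  computation is full precision.
* Statistics recomputed from published *rounded* per-pair columns can
  differ in the last digit from values originally computed on raw µm
  measurements; the shipped dataset objects document this.
* Problem sizes in the test suite (200 random karyotypes for the
  asymmetry oracle, exhaustive alignment enumeration to length 6 and an
  independent memoized-recursion oracle to length 12, 100 simulated
  amplicons for dissection round-trips) were chosen as the smallest sets
  that exercise every code path and tie-break while keeping the suite
  fast to run routinely.
* Homolog pairing is taken from the input table; automated karyotyping
  from raw lengths is out of scope, as is any image processing,
  multi-sequence alignment, or phylogenetic inference.
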