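"""5S rDNA repeat-unit dissection, alignment, and spacer statistics.

Plant 5S rDNA is organised as tandem repeats of a highly conserved
~120-bp gene (starting AGG, ending TCC) separated by a fast-evolving
non-transcribed spacer (NTS).  PCR with primers anchored inside the gene
amplifies across repeat-unit junctions, so an amplicon carries a 40-bp
tail of the gene at its 5' end and a 58-bp head of the gene at its 3'
end.  A *minor* amplicon spans one junction (gene tail + NTS + gene
head); a *major* amplicon spans two, containing a complete internal gene
between two NTS copies.

This module dissects such amplicons into their segments, locates the
intragenic RNA-polymerase-III promoter elements (A-box, intermediate
element, C-box), and compares NTS copies via an affine-gap global
aligner with GC-content, variable-site and identity statistics.

Coordinates are 0-based half-open internally and 1-based inclusive in
reports (the flat-file convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FLANK5_LEN",
    "FLANK3_LEN",
    "GENE_LEN",
    "DEFAULT_GENE_CONSENSUS",
    "RepeatAmplicon",
    "PromoterAnnotation",
    "NTSComparison",
    "AlignmentParams",
    "Alignment",
    "MotifConfig",
    "dissect_amplicon",
    "gc_content",
    "global_align",
    "count_variable_sites",
    "percent_identity",
    "compare_nts",
    "compare_nts_pairs",
    "find_promoter",
    "read_fasta",
    "write_fasta",
    "read_genbank",
]

FLANK5_LEN = 40  # gene 3' portion at the amplicon 5' end
FLANK3_LEN = 58  # gene 5' portion at the amplicon 3' end
GENE_LEN = 120

# A synthetic 120-bp 5S rRNA gene consensus with the canonical AGG...TCC
# frame and a type-1 Pol III internal control region (A-box, IE, C-box)
# at the canonical offsets; used as the default dissection/simulation
# reference, not a database sequence.
DEFAULT_GENE_CONSENSUS = (
    "AGGATGCGATCATACCAGCACTAATGCACC"
    "GGATCCCATCAGAACTCCGCAGTTAAGCG"
    "TGCTTGGGCGAGAGTAGTACT"
    "AGGATGGGTGACCTCCCGGGAAGTCC"
    "TTCGTGTTGCATCC"
)
assert len(DEFAULT_GENE_CONSENSUS) == GENE_LEN
assert DEFAULT_GENE_CONSENSUS.startswith("AGG")
assert DEFAULT_GENE_CONSENSUS.endswith("TCC")

Interval = tuple[int, int]  # 0-based half-open


class DissectionError(ValueError):
    """The amplicon cannot be reconciled with the repeat-unit structure."""


# ---------------------------------------------------------------------------
# dissection

@dataclass(frozen=True)
class RepeatAmplicon:
    """A 5S rDNA amplicon dissected into gene flanks, gene, and NTS segments."""

    seq_id: str
    sequence: str
    amplicon_class: str  # "minor" | "major"
    flank5: Interval
    nts1: Interval
    flank3: Interval
    gene: Interval | None = None  # major only
    nts2: Interval | None = None  # major only

    def segment(self, interval: Interval) -> str:
        return self.sequence[interval[0] : interval[1]]

    @property
    def segments(self) -> dict[str, str]:
        out = {
            "flank5": self.segment(self.flank5),
            "nts1": self.segment(self.nts1),
            "flank3": self.segment(self.flank3),
        }
        if self.gene is not None:
            out["gene"] = self.segment(self.gene)
        if self.nts2 is not None:
            out["nts2"] = self.segment(self.nts2)
        return out


def _best_ungapped_match(interior: str, consensus: str) -> tuple[int, float]:
    """Best sliding-window identity of consensus within interior."""
    n, m = len(interior), len(consensus)
    if n < m:
        return -1, 0.0
    a = np.frombuffer(interior.encode(), dtype=np.uint8)
    b = np.frombuffer(consensus.encode(), dtype=np.uint8)
    best_pos, best_frac = -1, -1.0
    for start in range(n - m + 1):
        frac = float(np.mean(a[start : start + m] == b))
        if frac > best_frac:
            best_pos, best_frac = start, frac
    return best_pos, best_frac


def dissect_amplicon(
    sequence: str,
    gene_consensus: str = DEFAULT_GENE_CONSENSUS,
    seq_id: str = "",
    min_gene_identity: float = 0.70,
    max_nts_length: int = 600,
) -> RepeatAmplicon:
    """Dissect an amplicon into flanks, NTS segment(s) and internal gene.

    The flanks are fixed at 40 bp (5') and 58 bp (3').  A complete
    internal gene, if present, is located by best ungapped match to
    ``gene_consensus`` and must keep the AGG...TCC frame; the amplicon is
    then classed *major* with two NTS segments, otherwise *minor* with a
    single NTS.  An interior longer than ``max_nts_length`` with no gene
    match is inconsistent with either class and raises.
    """
    sequence = sequence.upper().replace("U", "T")
    if len(sequence) <= FLANK5_LEN + FLANK3_LEN:
        raise DissectionError(
            f"amplicon of {len(sequence)} bp is shorter than the two gene flanks "
            f"({FLANK5_LEN} + {FLANK3_LEN} bp)"
        )
    if len(gene_consensus) != GENE_LEN:
        raise DissectionError(f"gene consensus must be {GENE_LEN} bp")
    interior = sequence[FLANK5_LEN : len(sequence) - FLANK3_LEN]
    pos, frac = _best_ungapped_match(interior, gene_consensus)
    flank5 = (0, FLANK5_LEN)
    flank3 = (len(sequence) - FLANK3_LEN, len(sequence))
    if pos >= 0 and frac >= min_gene_identity:
        gene_start = FLANK5_LEN + pos
        gene = (gene_start, gene_start + GENE_LEN)
        gene_seq = sequence[gene[0] : gene[1]]
        if not (gene_seq.startswith("AGG") and gene_seq.endswith("TCC")):
            raise DissectionError(
                f"internal gene match at {gene_start} violates the AGG...TCC frame"
            )
        if pos == 0 or gene[1] == flank3[0]:
            raise DissectionError(
                "internal gene abuts a flank; no NTS segment remains"
            )
        return RepeatAmplicon(
            seq_id=seq_id,
            sequence=sequence,
            amplicon_class="major",
            flank5=flank5,
            nts1=(FLANK5_LEN, gene[0]),
            gene=gene,
            nts2=(gene[1], flank3[0]),
            flank3=flank3,
        )
    # no internal gene: a minor amplicon spanning a single repeat junction
    if len(interior) > max_nts_length:
        raise DissectionError(
            f"no internal gene match above identity {min_gene_identity} and the "
            f"{len(interior)} bp interior exceeds a plausible single spacer "
            f"({max_nts_length} bp)"
        )
    return RepeatAmplicon(
        seq_id=seq_id,
        sequence=sequence,
        amplicon_class="minor",
        flank5=flank5,
        nts1=(FLANK5_LEN, flank3[0]),
        flank3=flank3,
    )


# ---------------------------------------------------------------------------
# composition statistics

_UNAMBIGUOUS = set("ACGT")


def gc_content(segment: str) -> float:
    """G+C percent of the unambiguous bases of a DNA segment.

    IUPAC ambiguity codes are excluded from both numerator and
    denominator.
    """
    if not segment:
        raise ValueError("empty segment")
    s = segment.upper().replace("U", "T")
    counted = [c for c in s if c in _UNAMBIGUOUS]
    if not counted:
        raise ValueError("segment has no unambiguous bases")
    gc = sum(c in "GC" for c in counted)
    return 100.0 * gc / len(counted)


# ---------------------------------------------------------------------------
# pairwise global alignment (affine gaps)

@dataclass(frozen=True)
class AlignmentParams:
    """Affine scoring: a length-L gap costs gap_open + (L-1) x gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned sequences differ in length")

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.a_aligned, self.b_aligned))


_NEG = float("-inf")


def global_align(a: str, b: str, params: AlignmentParams | None = None) -> Alignment:
    """Optimal global alignment under the affine-gap scheme (Gotoh DP).

    Tie-breaking is deterministic: diagonal is preferred over a gap in
    the second sequence (up), which is preferred over a gap in the first
    (left).
    """
    p = params or AlignmentParams()
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    # M: a_i aligned to b_j; X: gap in b (consumes a_i); Y: gap in a
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = p.gap_open + (j - 1) * p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] + p.gap_open,
                X[i - 1, j] + p.gap_extend,
                Y[i - 1, j] + p.gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] + p.gap_open,
                X[i, j - 1] + p.gap_open,
                Y[i, j - 1] + p.gap_extend,
            )

    # traceback, preferring diagonal, then up, then left at ties
    i, j = n, m
    finals = {"M": M[i, j], "X": X[i, j], "Y": Y[i, j]}
    state = max(("M", "X", "Y"), key=lambda k: (finals[k], k == "M", k == "X"))
    score = finals[state]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            target = M[i, j] - s
            prevs = {"M": M[i - 1, j - 1], "X": X[i - 1, j - 1], "Y": Y[i - 1, j - 1]}
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            prevs = {
                "M": M[i - 1, j] + p.gap_open,
                "X": X[i - 1, j] + p.gap_extend,
                "Y": Y[i - 1, j] + p.gap_open,
            }
            target = X[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:  # Y
            prevs = {
                "M": M[i, j - 1] + p.gap_open,
                "X": X[i, j - 1] + p.gap_open,
                "Y": Y[i, j - 1] + p.gap_extend,
            }
            target = Y[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if i == 0 and j == 0:
            break
        # pick the predecessor state matching the score, diagonal-first order
        for k in ("M", "X", "Y"):
            if np.isclose(prevs[k], target) and prevs[k] != _NEG:
                state = k
                break
        else:  # boundary cells
            state = "X" if j == 0 else "Y"
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


def _trim_terminal_gaps(alignment: Alignment) -> tuple[str, str]:
    """Drop leading/trailing columns where either sequence has a gap run."""
    a, b = alignment.a_aligned, alignment.b_aligned
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def count_variable_sites(alignment: Alignment) -> dict:
    """Variable columns and total columns after trimming terminal gaps.

    A column is variable when the residues differ or exactly one sequence
    has a gap; internal gap columns therefore count toward both the
    numerator and the denominator.
    """
    a, b = _trim_terminal_gaps(alignment)
    variable = sum(ca != cb for ca, cb in zip(a, b))
    return {"variable_sites": variable, "aligned_columns": len(a)}


def percent_identity(alignment: Alignment) -> float:
    """100 x matching columns / aligned columns (terminal gaps trimmed)."""
    counts = count_variable_sites(alignment)
    if counts["aligned_columns"] == 0:
        raise ValueError("alignment has no non-terminal-gap columns")
    return 100.0 * (1.0 - counts["variable_sites"] / counts["aligned_columns"])


@dataclass(frozen=True)
class NTSComparison:
    aligned_columns: int
    variable_sites: int
    identity: float
    gc_a: float
    gc_b: float


def compare_nts(a: str, b: str, params: AlignmentParams | None = None) -> NTSComparison:
    """Align two NTS sequences and report variability, identity and GC."""
    aln = global_align(a, b, params)
    counts = count_variable_sites(aln)
    return NTSComparison(
        aligned_columns=counts["aligned_columns"],
        variable_sites=counts["variable_sites"],
        identity=percent_identity(aln),
        gc_a=gc_content(a),
        gc_b=gc_content(b),
    )


def compare_nts_pairs(
    pair_5prime: tuple[str, str],
    pair_3prime: tuple[str, str],
    params: AlignmentParams | None = None,
) -> NTSComparison:
    """Concatenated comparison of matched 5' and 3' NTS regions.

    Cross-species spacer identity is reported over the two positionally
    matched alignments (5'NTS vs 5'NTS and 3'NTS vs 3'NTS); variable-site
    and column counts are summed before the identity is formed.
    """
    c1 = compare_nts(*pair_5prime, params=params)
    c2 = compare_nts(*pair_3prime, params=params)
    columns = c1.aligned_columns + c2.aligned_columns
    variable = c1.variable_sites + c2.variable_sites
    la, lb = len(pair_5prime[0]) + len(pair_3prime[0]), len(pair_5prime[1]) + len(pair_3prime[1])
    return NTSComparison(
        aligned_columns=columns,
        variable_sites=variable,
        identity=100.0 * (1.0 - variable / columns),
        gc_a=gc_content(pair_5prime[0] + pair_3prime[0]),
        gc_b=gc_content(pair_5prime[1] + pair_3prime[1]),
    )


# ---------------------------------------------------------------------------
# intragenic promoter

@dataclass(frozen=True)
class MotifConfig:
    """Consensus strings for the type-1 Pol III internal control region.

    Defaults are the corresponding windows of the package's gene
    consensus at the canonical element offsets (A-box near +50, IE near
    +67, C-box near +80); ``min_fraction`` is the matched-base fraction
    below which a motif is flagged absent.
    """

    a_box: str = DEFAULT_GENE_CONSENSUS[50:64]
    intermediate_element: str = DEFAULT_GENE_CONSENSUS[67:79]
    c_box: str = DEFAULT_GENE_CONSENSUS[80:97]
    min_fraction: float = 0.75


@dataclass(frozen=True)
class PromoterAnnotation:
    """Gene-local motif intervals (0-based half-open); None when absent."""

    a_box: Interval | None
    intermediate_element: Interval | None
    c_box: Interval | None
    scores: dict = field(default_factory=dict)


def _scan(gene: str, motif: str, start: int) -> tuple[int, float]:
    best_pos, best_frac = -1, -1.0
    for pos in range(start, len(gene) - len(motif) + 1):
        frac = sum(g == m for g, m in zip(gene[pos : pos + len(motif)], motif)) / len(motif)
        if frac > best_frac:
            best_pos, best_frac = pos, frac
    return best_pos, best_frac


def find_promoter(gene: str, motif_config: MotifConfig | None = None) -> PromoterAnnotation:
    """Locate the A-box, intermediate element and C-box within a 5S gene.

    Motifs are searched sequentially (each downstream of the previous
    hit) by best ungapped match; a motif scoring below the threshold is
    flagged absent rather than raising.
    """
    cfg = motif_config or MotifConfig()
    gene = gene.upper()
    intervals: dict[str, Interval | None] = {}
    scores: dict[str, float] = {}
    cursor = 0
    for name, motif in (
        ("a_box", cfg.a_box),
        ("intermediate_element", cfg.intermediate_element),
        ("c_box", cfg.c_box),
    ):
        pos, frac = _scan(gene, motif, cursor)
        scores[name] = max(frac, 0.0)
        if pos >= 0 and frac >= cfg.min_fraction:
            intervals[name] = (pos, pos + len(motif))
            cursor = pos + 1
        else:
            intervals[name] = None
    return PromoterAnnotation(
        a_box=intervals["a_box"],
        intermediate_element=intervals["intermediate_element"],
        c_box=intervals["c_box"],
        scores=scores,
    )


# ---------------------------------------------------------------------------
# sequence I/O (standard formats via Biopython)

def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_genbank(path) -> list[tuple[str, str]]:
    """Read GenBank flat files (e.g. locally saved accession records)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "genbank")]
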