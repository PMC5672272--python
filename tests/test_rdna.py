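"""5S rDNA amplicon dissection, alignment, spacer statistics, promoter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyotools.rdna_unit import (
    Alignment,
    AlignmentParams,
    DEFAULT_GENE_CONSENSUS,
    DissectionError,
    FLANK3_LEN,
    FLANK5_LEN,
    MotifConfig,
    compare_nts_pairs,
    count_variable_sites,
    dissect_amplicon,
    find_promoter,
    gc_content,
    global_align,
    percent_identity,
    read_fasta,
    read_genbank,
    write_fasta,
)
from karyotools.synthetic_data import RepeatSimConfig, simulate_amplicons

GENE = DEFAULT_GENE_CONSENSUS
FLANK5 = GENE[-FLANK5_LEN:]
FLANK3 = GENE[:FLANK3_LEN]


def build_amplicon(*nts_segments):
    """Assemble an amplicon with the given NTS segment(s) around the gene."""
    if len(nts_segments) == 1:
        return FLANK5 + nts_segments[0] + FLANK3
    nts1, nts2 = nts_segments
    return FLANK5 + nts1 + GENE + nts2 + FLANK3


def random_nts(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestDissection:
    def test_minor_amplicon_yields_full_nts(self):
        rng = np.random.default_rng(0)
        amp = dissect_amplicon(build_amplicon(random_nts(rng, 361)))
        assert amp.amplicon_class == "minor"
        assert len(amp.segment(amp.nts1)) == 361
        assert len(amp.sequence) == 459

    def test_major_amplicon_equal_spacers(self):
        rng = np.random.default_rng(1)
        seq = build_amplicon(random_nts(rng, 361), random_nts(rng, 361))
        amp = dissect_amplicon(seq)
        assert amp.amplicon_class == "major"
        lengths = {k: len(v) for k, v in amp.segments.items()}
        assert lengths == {"flank5": 40, "nts1": 361, "gene": 120, "nts2": 361, "flank3": 58}
        assert len(seq) == 940

    def test_major_amplicon_unequal_spacers(self):
        rng = np.random.default_rng(2)
        seq = build_amplicon(random_nts(rng, 359), random_nts(rng, 371))
        amp = dissect_amplicon(seq)
        assert len(seq) == 948
        assert len(amp.segment(amp.nts1)) == 359
        assert len(amp.segment(amp.nts2)) == 371

    def test_segments_tile_the_sequence(self):
        rng = np.random.default_rng(3)
        seq = build_amplicon(random_nts(rng, 200), random_nts(rng, 250))
        amp = dissect_amplicon(seq)
        assert sum(len(v) for v in amp.segments.values()) == len(seq)
        intervals = sorted(
            [amp.flank5, amp.nts1, amp.gene, amp.nts2, amp.flank3]
        )
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 == b0  # contiguous, non-overlapping

    def test_gene_found_despite_divergence(self):
        rng = np.random.default_rng(4)
        gene = list(GENE)
        for pos in rng.choice(np.arange(3, 117), 12, replace=False):
            gene[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[gene[pos]]
        seq = FLANK5 + random_nts(rng, 300) + "".join(gene) + random_nts(rng, 300) + FLANK3
        amp = dissect_amplicon(seq)
        assert amp.amplicon_class == "major"
        assert len(amp.segment(amp.gene)) == 120

    def test_overlong_interior_without_gene_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(DissectionError, match="spacer"):
            dissect_amplicon(build_amplicon(random_nts(rng, 800)))

    def test_too_short_amplicon_rejected(self):
        with pytest.raises(DissectionError, match="flank"):
            dissect_amplicon("ACGT" * 10)


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_codes_excluded(self):
        assert gc_content("GGNNCCRR") == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_invariant_under_reverse_complement(self, seq):
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert gc_content(seq) == pytest.approx(gc_content(rc))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


def enumerate_alignments(a, b):
    """All global alignments as (a_aligned, b_aligned) pairs, brute force."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ta, tb in enumerate_alignments(a[1:], b):
            yield (a[0] + ta, "-" + tb)
    if b:
        for ta, tb in enumerate_alignments(a, b[1:]):
            yield ("-" + ta, b[0] + tb)
    if a and b:
        for ta, tb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ta, b[0] + tb)


def score_alignment(aa, bb, p):
    """Affine score of an explicit alignment (first gap char pays gap_open)."""
    score = 0.0
    prev = None  # 'a' = gap in a, 'b' = gap in b
    for ca, cb in zip(aa, bb):
        if ca == "-":
            score += p.gap_extend if prev == "a" else p.gap_open
            prev = "a"
        elif cb == "-":
            score += p.gap_extend if prev == "b" else p.gap_open
            prev = "b"
        else:
            score += p.match if ca == cb else p.mismatch
            prev = None
    return score


def recursive_oracle(a, b, p):
    """Max alignment score by memoized recursion over (i, j, gap state)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] else p.mismatch
            options.append(s + best(i + 1, j + 1, None))
        if i < len(a):
            cost = p.gap_extend if state == "b" else p.gap_open
            options.append(cost + best(i + 1, j, "b"))
        if j < len(b):
            cost = p.gap_extend if state == "a" else p.gap_open
            options.append(cost + best(i, j + 1, "a"))
        return max(options)

    return best(0, 0, None)


class TestAligner:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert "-" not in aln.a_aligned + aln.b_aligned
        assert percent_identity(aln) == pytest.approx(100.0)

    def test_single_deletion_linear_gaps(self):
        aln = global_align("ACGT", "ACT", AlignmentParams(1, -1, -2, -2))
        assert aln.score == pytest.approx(1.0)
        assert sum(c == "-" for c in aln.b_aligned) == 1

    def test_exhaustive_enumeration_small(self):
        p = AlignmentParams()
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = random_nts(rng, rng.integers(0, 7))
            b = random_nts(rng, rng.integers(0, 7))
            if not a and not b:
                continue
            best = max(
                score_alignment(aa, bb, p) for aa, bb in enumerate_alignments(a, b)
            )
            aln = global_align(a, b, p)
            assert aln.score == pytest.approx(best), (a, b)
            assert score_alignment(aln.a_aligned, aln.b_aligned, p) == pytest.approx(best)

    def test_recursive_oracle_up_to_length_12(self):
        p = AlignmentParams()
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = random_nts(rng, rng.integers(1, 13))
            b = random_nts(rng, rng.integers(1, 13))
            aln = global_align(a, b, p)
            assert aln.score == pytest.approx(recursive_oracle(a, b, p)), (a, b)

    def test_biopython_cross_check(self):
        from Bio import Align

        ref = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-4,
            extend_gap_score=-1,
        )
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = random_nts(rng, 50)
            b = random_nts(rng, rng.integers(40, 60))
            assert global_align(a, b).score == pytest.approx(ref.score(a, b))

    def test_traceback_reproduces_the_reported_score(self):
        p = AlignmentParams()
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = random_nts(rng, 30)
            b = random_nts(rng, 25)
            aln = global_align(a, b, p)
            assert score_alignment(aln.a_aligned, aln.b_aligned, p) == pytest.approx(aln.score)


class TestColumnStatistics:
    def test_identical_sequences_have_no_variable_sites(self):
        counts = count_variable_sites(global_align("ACGTT", "ACGTT"))
        assert counts == {"variable_sites": 0, "aligned_columns": 5}

    def test_internal_gap_counts_as_variable(self):
        aln = Alignment("AC-GT", "ACTGT", 0.0)
        counts = count_variable_sites(aln)
        assert counts == {"variable_sites": 1, "aligned_columns": 5}
        assert percent_identity(aln) == pytest.approx(80.0)

    def test_terminal_gaps_trimmed(self):
        aln = Alignment("--ACGT", "GGACGT", 0.0)
        assert count_variable_sites(aln) == {"variable_sites": 0, "aligned_columns": 4}

    def test_identity_complements_variability(self):
        rng = np.random.default_rng(11)
        a, b = random_nts(rng, 80), random_nts(rng, 75)
        aln = global_align(a, b)
        counts = count_variable_sites(aln)
        expected = 100.0 * (1 - counts["variable_sites"] / counts["aligned_columns"])
        assert percent_identity(aln) == pytest.approx(expected, abs=1e-12)

    def test_fully_mismatched_pair(self):
        aln = Alignment("AAAA", "TTTT", 0.0)
        assert percent_identity(aln) == pytest.approx(0.0)

    def test_published_identity_arithmetic(self):
        # 145 variable sites over 736 concatenated columns -> 80.3%
        assert 100.0 * (1 - 145 / 736) == pytest.approx(80.3, abs=0.05)

    def test_concatenated_pair_comparison(self):
        rng = np.random.default_rng(12)
        a5, b5 = random_nts(rng, 40), random_nts(rng, 40)
        a3, b3 = random_nts(rng, 50), random_nts(rng, 55)
        combined = compare_nts_pairs((a5, b5), (a3, b3))
        from karyotools.rdna_unit import compare_nts

        c5, c3 = compare_nts(a5, b5), compare_nts(a3, b3)
        assert combined.aligned_columns == c5.aligned_columns + c3.aligned_columns
        assert combined.variable_sites == c5.variable_sites + c3.variable_sites
        assert combined.identity == pytest.approx(
            100.0 * (1 - combined.variable_sites / combined.aligned_columns)
        )


class TestPromoter:
    def test_planted_motifs_recovered_exactly(self):
        annotation = find_promoter(GENE)
        cfg = MotifConfig()
        assert annotation.a_box == (50, 50 + len(cfg.a_box))
        assert annotation.intermediate_element == (67, 67 + len(cfg.intermediate_element))
        assert annotation.c_box == (80, 80 + len(cfg.c_box))
        assert all(s == pytest.approx(1.0) for s in annotation.scores.values())

    def test_single_mutation_keeps_interval_lowers_score(self):
        gene = list(GENE)
        gene[52] = "A" if gene[52] != "A" else "C"
        annotation = find_promoter("".join(gene))
        assert annotation.a_box == (50, 64)
        assert annotation.scores["a_box"] < 1.0

    def test_scrambled_sequence_flags_all_absent(self):
        rng = np.random.default_rng(13)
        scrambled = random_nts(rng, 120)
        annotation = find_promoter(scrambled)
        assert annotation.a_box is None
        assert annotation.intermediate_element is None
        assert annotation.c_box is None

    def test_element_order_enforced(self):
        annotation = find_promoter(GENE)
        assert annotation.a_box[0] < annotation.intermediate_element[0] < annotation.c_box[0]


class TestSequenceIO:
    def test_fasta_round_trip(self, tmp_path):
        records, _ = simulate_amplicons(RepeatSimConfig(seed=1))
        path = tmp_path / "amps.fasta"
        write_fasta(records, path)
        loaded = read_fasta(path)
        assert loaded == records

    def test_genbank_reader(self, tmp_path):
        # minimal synthetic flat file exercising the standard-format path
        seq = build_amplicon("ACGT" * 25)
        body = "\n".join(
            " ".join([f"{i+1:>9}"] + [seq[i + j : i + j + 10].lower() for j in range(0, 60, 10)])
            for i in range(0, len(seq), 60)
        )
        gb = (
            f"LOCUS       {'SYNTH0001':<16}{len(seq):>11} bp    DNA     linear   PLN 01-JAN-2016\n"
            "DEFINITION  synthetic 5S rDNA repeat-unit amplicon.\n"
            "ACCESSION   SYNTH0001\n"
            "VERSION     SYNTH0001.1\n"
            "FEATURES             Location/Qualifiers\n"
            f"     source          1..{len(seq)}\n"
            "ORIGIN\n"
            f"{body}\n"
            "//\n"
        )
        path = tmp_path / "synthetic.gb"
        path.write_text(gb)
        records = read_genbank(path)
        assert len(records) == 1
        assert records[0][1].upper() == seq
        amp = dissect_amplicon(records[0][1], seq_id=records[0][0])
        assert amp.amplicon_class == "minor"
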