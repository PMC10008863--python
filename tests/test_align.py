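"""Alignment engine: scoring schemes, complementation, OMS determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronmatch.align import (
    ALPHABET,
    ScoringScheme,
    complement,
    find_oms,
    get_scheme,
    local_align,
    score_alignment,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


# ---------------------------------------------------------------- complement


@pytest.mark.parametrize(
    "seq,reverse,expected",
    [
        ("ACGT", False, "TGCA"),
        ("ACGT", True, "ACGT"),  # palindromic reverse complement
        ("TGCA", False, "ACGT"),
        ("acgu", False, "TGCA"),  # U folded into T, uppercased
        ("RYSWKMN", False, "YRSWMKN"),
    ],
)
def test_complement_examples(seq, reverse, expected):
    assert complement(seq, reverse=reverse) == expected


def test_complement_rejects_bad_symbol_with_position():
    with pytest.raises(ValueError, match="position 3"):
        complement("ACXG")


@given(dna)
def test_complement_is_an_involution(seq):
    assert complement(complement(seq)) == seq


# ------------------------------------------------------------------ schemes


def test_bfe_pair_scores(bfe):
    assert bfe.pair_score("A", "A") == 5
    assert bfe.pair_score("T", "T") == 5
    assert bfe.pair_score("G", "G") == 6
    assert bfe.pair_score("C", "C") == 6
    for x, y in [("A", "C"), ("A", "G"), ("A", "T"), ("G", "T"), ("N", "N"), ("A", "N")]:
        assert bfe.pair_score(x, y) == -4


def test_sw_matches_published_ednafull(sw):
    from Bio.Align import substitution_matrices

    nuc44 = substitution_matrices.load("NUC.4.4")
    for x in ALPHABET:
        for y in ALPHABET:
            assert sw.pair_score(x, y) == int(nuc44[x, y])


def test_bfe_symmetry(bfe):
    m = bfe.matrix
    assert np.array_equal(m, m.T)


def test_gap_penalties(bfe, sw):
    for s in (bfe, sw):
        assert s.gap_open == 50 and s.gap_extend == 5


def test_get_scheme_rejects_unknown():
    with pytest.raises(ValueError, match="unknown scoring scheme"):
        get_scheme("nope")


# -------------------------------------------------------------- local_align


def test_local_align_embedded_segment(bfe):
    oms = local_align("GGACGTGG", "ACGT", bfe)
    assert oms.score == 22  # 5 + 6 + 6 + 5
    assert (oms.tested_start, oms.tested_end) == (3, 6)
    assert oms.n_identities == 4 and oms.n_gap_columns == 0


def test_local_align_full_match(bfe):
    oms = local_align("AAAA", "AAAA", bfe)
    assert oms.score == 20
    assert (oms.tested_start, oms.tested_end) == (1, 4)


def test_local_align_single_column(bfe):
    oms = local_align("ACGT", "TTTT", bfe)
    assert oms.score == 5
    assert oms.tested_start == oms.tested_end == 4


def test_local_align_empty_sentinel(bfe):
    # no positive-scoring column: A vs C only
    oms = local_align("AAAA", "CCCC", bfe)
    assert oms.score == 0 and oms.is_empty


def test_local_align_rejects_empty_sequence(bfe):
    with pytest.raises(ValueError):
        local_align("", "ACGT", bfe)


def test_tie_break_prefers_smallest_tested_then_aligned_end(bfe):
    # two identical best segments on the tested side -> earlier one reported
    oms = local_align("ACGTTTACGT", "ACGT", bfe)
    assert (oms.tested_start, oms.tested_end) == (1, 4)
    oms2 = local_align("ACGT", "ACGTTTACGT", bfe)
    assert (oms2.intron_start, oms2.intron_end) == (1, 4)


# ----------------------------------------------------------------- find_oms


def test_find_oms_maps_back_to_original_intron(bfe):
    oms = find_oms("GGACGTGG", "TGCA", bfe)  # complement of TGCA is ACGT
    assert oms.score == 22
    assert (oms.tested_start, oms.tested_end) == (3, 6)
    assert (oms.intron_start, oms.intron_end) == (1, 4)
    assert oms.orientation == "complement"


def test_find_oms_reverse_complement_of_palindrome(bfe):
    # ACGT is its own reverse complement, so the mRNA's ACGT block matches
    b = find_oms("GGACGTGG", "ACGT", bfe, orientation="reverse_complement")
    assert b.score == 22
    # a plain complement turns ACGT into TGCA, which has no 4-base match here
    a = find_oms("GGACGTGG", "ACGT", bfe, orientation="complement")
    assert a.score < 22


def test_find_oms_reverse_complement_coordinates(bfe):
    # intron CCCCTGCA: reverse complement is TGCAGGGG; mRNA carries TGCA
    oms = find_oms("AATGCAAA", "CCCCTGCA", bfe, orientation="reverse_complement")
    assert (oms.tested_start, oms.tested_end) == (3, 6)
    # matched block sits on intron positions 5..8 of the ORIGINAL intron
    assert (oms.intron_start, oms.intron_end) == (5, 8)


def test_find_oms_deterministic(bfe):
    rng = np.random.default_rng(42)
    for _ in range(10):
        m = random_dna(rng, 80)
        i = random_dna(rng, 40)
        a = find_oms(m, i, bfe)
        b = find_oms(m, i, bfe)
        assert a == b


def test_find_oms_rejects_bad_orientation(bfe):
    with pytest.raises(ValueError):
        find_oms("ACGT", "ACGT", bfe, orientation="sideways")


# ---------------------------------------------------------- score_alignment


@pytest.mark.parametrize(
    "t,a,scheme_name,expected",
    [
        ("ACGT", "ACGT", "BFE", 22),
        ("A-T", "AAT", "BFE", -40),  # 5 + 5 - 50
        ("G", "G", "SW", 5),
        ("AC--T", "ACGGT", "BFE", 5 + 6 - 50 - 5 + 5),
    ],
)
def test_score_alignment_examples(t, a, scheme_name, expected):
    assert score_alignment(t, a, get_scheme(scheme_name)) == expected


def test_score_alignment_rejects_double_gap_and_mismatch(bfe):
    with pytest.raises(ValueError, match="double-gap"):
        score_alignment("A-G", "A-G", bfe)
    with pytest.raises(ValueError, match="length"):
        score_alignment("AC", "A", bfe)


def test_oms_score_self_consistent(bfe, sw):
    rng = np.random.default_rng(7)
    for scheme in (bfe, sw):
        for _ in range(25):
            m = random_dna(rng, 120)
            i = random_dna(rng, 60)
            oms = find_oms(m, i, scheme)
            if not oms.is_empty:
                assert score_alignment(oms.tested_aln, oms.aligned_aln, scheme) == oms.score
                assert oms.n_identities <= oms.n_columns - oms.n_gap_columns


# --------------------------------------------------------------- properties


def _ungapped_best(t: str, a: str, scheme: ScoringScheme) -> int:
    """Exhaustive max over all ungapped substring alignments.

    Exact for sequences up to 12 bases: any gapped alignment decomposes
    into >= 2 maximal ungapped blocks on disjoint columns, whose summed
    pair scores are at most 6 * min(n, m) <= 72, minus >= 50 per gap, so
    a gapped alignment can never exceed the best ungapped score at this
    size and the optimal local score is achieved gaplessly.
    """
    best = 0
    for i in range(len(t)):
        for j in range(len(a)):
            s = 0
            for k in range(min(len(t) - i, len(a) - j)):
                s += scheme.pair_score(t[i + k], a[j + k])
                best = max(best, s)
    return best


@settings(max_examples=150, deadline=None)
@given(st.data())
def test_oracle_equivalence_small(bfe, sw, data):
    t = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=8))
    a = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=8))
    for scheme in (bfe, sw):
        oms = local_align(t, a, scheme)
        assert oms.score == _ungapped_best(t, a, scheme)
        assert oms.n_gap_columns == 0  # gap_open dominates at this size


def test_oracle_equivalence_biopython(bfe, sw):
    """Cross-library check against Bio.Align.PairwiseAligner, lengths <= 12."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    rng = np.random.default_rng(2024)
    for scheme in (bfe, sw):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        mat = substitution_matrices.Array(
            "ACGT",
            dims=2,
            data=np.array(
                [[scheme.pair_score(x, y) for y in "ACGT"] for x in "ACGT"],
                dtype=float,
            ),
        )
        aligner.substitution_matrix = mat
        aligner.open_gap_score = -scheme.gap_open
        aligner.extend_gap_score = -scheme.gap_extend
        for _ in range(300):
            t = random_dna(rng, int(rng.integers(1, 13)))
            a = random_dna(rng, int(rng.integers(1, 13)))
            ours = local_align(t, a, scheme).score
            assert ours == int(aligner.score(t, a))


@settings(max_examples=60, deadline=None)
@given(dna, dna, st.text(alphabet="ACGT", min_size=1, max_size=4))
def test_score_monotone_under_extension(bfe, t, a, extra):
    base = local_align(t, a, bfe).score
    assert local_align(t + extra, a, bfe).score >= base
    assert local_align(t, extra + a, bfe).score >= base


def test_bfe_bracketed_by_uniform_schemes(bfe):
    """On fixed columns, uniform(+5) <= BFE <= uniform(+6) rescoring."""
    lo = np.full((15, 15), -4, dtype=np.int64)
    hi = np.full((15, 15), -4, dtype=np.int64)
    for b in "ACGT":
        i = "ACGTRYSWKMBDHVN".index(b)
        lo[i, i] = 5
        hi[i, i] = 6
    s_lo = ScoringScheme("U5", lo)
    s_hi = ScoringScheme("U6", hi)
    rng = np.random.default_rng(5)
    for _ in range(20):
        m = random_dna(rng, 100)
        i = random_dna(rng, 50)
        oms = find_oms(m, i, bfe)
        if oms.is_empty:
            continue
        mid = score_alignment(oms.tested_aln, oms.aligned_aln, bfe)
        assert (
            score_alignment(oms.tested_aln, oms.aligned_aln, s_lo)
            <= mid
            <= score_alignment(oms.tested_aln, oms.aligned_aln, s_hi)
        )
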