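"""Local alignment of mRNAs against complemented introns.

The screening idea: if a post-spliced intron can base-pair with its own
mature mRNA, then the complement of the intron contains a segment that is
*similar* to a segment of the mRNA.  We therefore complement the intron,
run a Smith-Waterman local alignment (affine gaps, Gotoh three-state
recurrence) of the mRNA ("tested" sequence) against the complemented
intron ("aligned" sequence), and map the single best-scoring segment — the
optimal matched segment (OMS) — back onto the original intron.

Two scoring schemes are built in:

``SW``
    The standard EDNAFULL (NUC.4.4) nucleotide matrix: +5 for a match,
    -4 for a mismatch between canonical bases, published values for IUPAC
    ambiguity codes.

``BFE``
    A binding-free-energy weighting.  In complemented space an identical
    A/T column corresponds to an original A-T or T-A pair (two hydrogen
    bonds) and scores +5; an identical G/C column corresponds to a G-C or
    C-G pair (three hydrogen bonds) and scores +6; every non-complementary
    pairing scores -4.  The 5:6 asymmetry mirrors the roughly 2:3 ratio of
    A-T to G-C pairing energies.  Base stacking is not modelled.

Both schemes use affine gap penalties of 50 (open) and 5 (extend): a gap
of length g costs 50 + (g-1)*5, the EMBOSS ``water`` convention.  All
scores are integers so alignment results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "ScoringScheme",
    "OptimalMatchedSegment",
    "bfe_scheme",
    "sw_scheme",
    "get_scheme",
    "complement",
    "local_align",
    "find_oms",
    "score_alignment",
]

# IUPAC DNA alphabet used for encoding; U is folded into T on input.
ALPHABET = "ACGTRYSWKMBDHVN"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

GAP_OPEN = 50
GAP_EXTEND = 5

_NEG = -(1 << 40)


@dataclass(frozen=True)
class ScoringScheme:
    """A pair-score table plus affine gap penalties.

    ``matrix`` is indexed by the position of each symbol in :data:`ALPHABET`.
    ``gap_open`` is charged for the first position of each gap and
    ``gap_extend`` for every further position.
    """

    name: str
    matrix: np.ndarray = field(repr=False)
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND

    def pair_score(self, x: str, y: str) -> int:
        """Score of one aligned (gap-free) column."""
        return int(self.matrix[_INDEX[_canon(x)], _INDEX[_canon(y)]])


def _canon(c: str) -> str:
    c = c.upper()
    if c == "U":
        c = "T"
    if c not in _INDEX:
        raise ValueError(f"non-IUPAC nucleotide symbol {c!r}")
    return c


def _build_bfe() -> np.ndarray:
    m = np.full((15, 15), -4, dtype=np.int64)
    for b, s in (("A", 5), ("T", 5), ("G", 6), ("C", 6)):
        i = _INDEX[b]
        m[i, i] = s
    return m


def _build_ednafull() -> np.ndarray:
    nuc44 = substitution_matrices.load("NUC.4.4")
    m = np.zeros((15, 15), dtype=np.int64)
    for x in ALPHABET:
        for y in ALPHABET:
            m[_INDEX[x], _INDEX[y]] = int(nuc44[x, y])
    return m


def bfe_scheme() -> ScoringScheme:
    """Binding-free-energy weighted scheme (+5 A/T, +6 G/C, -4 mismatch)."""
    return ScoringScheme("BFE", _build_bfe())


def sw_scheme() -> ScoringScheme:
    """Classic EDNAFULL (NUC.4.4) scheme (+5 match, -4 mismatch)."""
    return ScoringScheme("SW", _build_ednafull())


_SCHEMES = {"BFE": bfe_scheme, "SW": sw_scheme}


def get_scheme(name: str) -> ScoringScheme:
    try:
        return _SCHEMES[name.upper()]()
    except KeyError:
        raise ValueError(f"unknown scoring scheme {name!r}; choose from {sorted(_SCHEMES)}") from None


def complement(seq: str, reverse: bool = False) -> str:
    """Watson-Crick complement of ``seq``; reversed as well iff ``reverse``.

    U is treated as T; IUPAC ambiguity codes are complemented per the
    standard table; output is uppercase.  A non-IUPAC symbol raises
    ``ValueError`` with its (1-based) position.
    """
    out = []
    for pos, c in enumerate(seq, start=1):
        u = c.upper()
        if u == "U":
            u = "T"
        try:
            out.append(_COMPLEMENT[u])
        except KeyError:
            raise ValueError(f"non-IUPAC symbol {c!r} at position {pos}") from None
    if reverse:
        out.reverse()
    return "".join(out)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into alphabet indices (uint8), folding U into T."""
    arr = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq):
        u = c.upper()
        if u == "U":
            u = "T"
        try:
            arr[i] = _INDEX[u]
        except KeyError:
            raise ValueError(f"non-IUPAC symbol {c!r} at position {i + 1}") from None
    return arr


@dataclass(frozen=True)
class OptimalMatchedSegment:
    """The single best local alignment between an mRNA and one intron.

    ``tested_start``/``tested_end`` are 1-based inclusive positions on the
    mRNA.  ``intron_start``/``intron_end`` are 1-based inclusive positions
    on the ORIGINAL intron (complementation and any reversal undone); for a
    bare :func:`local_align` call they refer to the aligned sequence as
    given.  An empty segment (no positive-scoring column exists) has score
    0 and all coordinates 0.
    """

    tested_id: str
    aligned_id: str
    tested_start: int
    tested_end: int
    intron_start: int
    intron_end: int
    score: int
    n_identities: int
    n_columns: int
    n_gap_columns: int
    tested_aln: str
    aligned_aln: str
    scheme_name: str
    orientation: str = "complement"

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0

    @property
    def tested_length(self) -> int:
        """Length of the matched segment on the (ungapped) mRNA."""
        return 0 if self.is_empty else self.tested_end - self.tested_start + 1

    @property
    def match_rate(self) -> float:
        """Percent identical columns; undefined (NaN) for the empty segment."""
        if self.is_empty:
            return float("nan")
        return 100.0 * self.n_identities / self.n_columns


@njit(cache=True)
def _gotoh(t, a, S, go, ge):  # pragma: no cover - exercised via local_align
    n = t.shape[0]
    m = a.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), _NEG, np.int64)
    F = np.full((n + 1, m + 1), _NEG, np.int64)
    pH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    pE = np.zeros((n + 1, m + 1), np.uint8)  # 0 open-from-H, 1 extend
    pF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - go
            ee = E[i, j - 1] - ge
            if ee > eo:  # tie -> close the gap (shorter gaps win)
                E[i, j] = ee
                pE[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - go
            fe = F[i - 1, j] - ge
            if fe > fo:
                F[i, j] = fe
                pF[i, j] = 1
            else:
                F[i, j] = fo
            d = H[i - 1, j - 1] + S[t[i - 1], a[j - 1]]
            h = 0
            p = 0
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if F[i, j] > h or (F[i, j] == h and p == 3):  # up beats left on ties
                h = F[i, j]
                p = 2
            if d > h or (d == h and p != 0):  # diagonal beats both
                h = d
                p = 1
            H[i, j] = h
            pH[i, j] = p
            if h > best:  # strict > with row-major scan -> smallest (i, j) tie-break
                best = h
                bi = i
                bj = j
    moves = np.empty(n + m, np.uint8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E (gap in tested), 2=F (gap in aligned)
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                moves[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            moves[k] = 3
            k += 1
            if pE[i, j] == 0:
                state = 0
            j -= 1
        else:
            moves[k] = 2
            k += 1
            if pF[i, j] == 0:
                state = 0
            i -= 1
    return best, bi, bj, i, j, moves[:k]


def local_align(
    tested: str,
    aligned: str,
    scheme: ScoringScheme,
    tested_id: str = "tested",
    aligned_id: str = "aligned",
) -> OptimalMatchedSegment:
    """Single optimal local alignment of ``tested`` against ``aligned``.

    Deterministic tie-breaking: among equal-scoring end cells the smallest
    tested end coordinate wins, then the smallest aligned end coordinate;
    in traceback diagonal is preferred over a gap in the aligned sequence,
    which is preferred over a gap in the tested sequence.

    Returns the empty sentinel (score 0, zero length) only when no
    positive-scoring column exists.
    """
    if not tested or not aligned:
        raise ValueError("sequences must be non-empty")
    t = encode(tested)
    a = encode(aligned)
    score, bi, bj, si, sj, rmoves = _gotoh(
        t, a, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    score = int(score)
    if score == 0:
        return OptimalMatchedSegment(
            tested_id, aligned_id, 0, 0, 0, 0, 0, 0, 0, 0, "", "", scheme.name
        )
    moves = rmoves[::-1]
    tcols = []
    acols = []
    ti = si
    aj = sj
    n_gap = 0
    n_id = 0
    tu = tested.upper().replace("U", "T")
    au = aligned.upper().replace("U", "T")
    for mv in moves:
        if mv == 1:
            x = tu[ti]
            y = au[aj]
            tcols.append(x)
            acols.append(y)
            if x == y:
                n_id += 1
            ti += 1
            aj += 1
        elif mv == 2:  # gap in aligned
            tcols.append(tu[ti])
            acols.append("-")
            n_gap += 1
            ti += 1
        else:  # gap in tested
            tcols.append("-")
            acols.append(au[aj])
            n_gap += 1
            aj += 1
    return OptimalMatchedSegment(
        tested_id=tested_id,
        aligned_id=aligned_id,
        tested_start=si + 1,
        tested_end=int(bi),
        intron_start=sj + 1,
        intron_end=int(bj),
        score=score,
        n_identities=n_id,
        n_columns=len(moves),
        n_gap_columns=n_gap,
        tested_aln="".join(tcols),
        aligned_aln="".join(acols),
        scheme_name=scheme.name,
    )


def find_oms(
    mrna: str,
    intron: str,
    scheme: ScoringScheme,
    orientation: str = "complement",
    mrna_id: str = "mrna",
    intron_id: str = "intron",
) -> OptimalMatchedSegment:
    """OMS of an (mRNA, intron) pair, in original-intron coordinates.

    The intron is complemented (``orientation="complement"``) or
    reverse-complemented (``orientation="reverse_complement"``), the mRNA is
    locally aligned against it, and the aligned-side interval is mapped back
    onto the original intron.
    """
    if orientation not in ("complement", "reverse_complement"):
        raise ValueError(f"unknown orientation {orientation!r}")
    reverse = orientation == "reverse_complement"
    cintron = complement(intron, reverse=reverse)
    oms = local_align(mrna, cintron, scheme, tested_id=mrna_id, aligned_id=intron_id)
    if oms.is_empty:
        return OptimalMatchedSegment(
            mrna_id, intron_id, 0, 0, 0, 0, 0, 0, 0, 0, "", "", scheme.name, orientation
        )
    if reverse:
        L = len(intron)
        i_start = L - oms.intron_end + 1
        i_end = L - oms.intron_start + 1
    else:
        i_start, i_end = oms.intron_start, oms.intron_end
    return OptimalMatchedSegment(
        tested_id=mrna_id,
        aligned_id=intron_id,
        tested_start=oms.tested_start,
        tested_end=oms.tested_end,
        intron_start=i_start,
        intron_end=i_end,
        score=oms.score,
        n_identities=oms.n_identities,
        n_columns=oms.n_columns,
        n_gap_columns=oms.n_gap_columns,
        tested_aln=oms.tested_aln,
        aligned_aln=oms.aligned_aln,
        scheme_name=scheme.name,
        orientation=orientation,
    )


def score_alignment(tested_aln: str, aligned_aln: str, scheme: ScoringScheme) -> int:
    """Re-score a gapped alignment column by column (self-consistency check).

    A gap of length g costs ``gap_open + (g-1)*gap_extend``.  Rejects
    length mismatches and columns that are gaps on both sides.
    """
    if len(tested_aln) != len(aligned_aln):
        raise ValueError("gapped strings differ in length")
    score = 0
    in_gap_t = False
    in_gap_a = False
    for col, (x, y) in enumerate(zip(tested_aln, aligned_aln), start=1):
        if x == "-" and y == "-":
            raise ValueError(f"double-gap column at position {col}")
        if x == "-":
            score -= scheme.gap_extend if in_gap_t else scheme.gap_open
            in_gap_t = True
            in_gap_a = False
        elif y == "-":
            score -= scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a = True
            in_gap_t = False
        else:
            score += scheme.pair_score(x, y)
            in_gap_t = in_gap_a = False
    return score
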