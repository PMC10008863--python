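"""Sequence characteristics of matched segments and sequence classes.

Covers the four descriptive features used to characterize optimal matched
segments: match rate, segment length, G+C content, and the second-order
informational redundancy D2.  D2 is the mutual information (in bits)
between adjacent bases,

    D2 = sum_ij p_ij * log2( p_ij / (p_i * p_j) ),

with p_i the mononucleotide and p_ij the adjacent-dinucleotide
probabilities estimated from counts (pairs are counted within each
sequence only, never across sequence boundaries).  D2 = 0 for an
infinitely long independent-base sequence; for a finite sequence of N
bases the 99%-confidence fluctuation bound is 15.65 / N, which matches
the chi-square(9 df) quantile 21.67 / (2 ln 2) = 15.63 of the quadratic
approximation D2 ~ sum_ij (p_ij - p_i p_j)^2 / (2 ln2 * p_i p_j).
An observed D2 at or above the bound indicates real adjacent-base
correlation at the 99% level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import OptimalMatchedSegment

__all__ = [
    "D2Result",
    "match_rate",
    "gc_content",
    "d2_redundancy",
    "d2_approx",
    "d2_bound",
    "class_statistics",
]

D2_BOUND_CONSTANT = 15.65
_BASES = "ACGT"
_BASE_INDEX = {c: i for i, c in enumerate(_BASES)}


def match_rate(oms: OptimalMatchedSegment) -> float:
    """Percent identical columns in the OMS alignment (0, 100]."""
    if oms.is_empty:
        raise ValueError("match rate undefined for an empty segment")
    return 100.0 * oms.n_identities / oms.n_columns


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); ambiguity symbols are excluded."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / total


@dataclass(frozen=True)
class D2Result:
    """Second-order informational redundancy with its fluctuation bound."""

    d2: float  # bits, clipped at 0
    n_bases: int
    n_pairs_counted: int
    fluctuation_bound: float  # 15.65 / n_bases
    significant: bool  # d2 >= bound
    mode: str = "pooled"
    d2_approx: float = float("nan")  # quadratic (chi-square) approximation


def _counts(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Mono- and adjacent-dinucleotide counts of one sequence (ACGT only)."""
    s = seq.upper().replace("U", "T")
    idx = np.full(len(s), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = i
    mono = np.bincount(idx[idx >= 0], minlength=4).astype(np.float64)
    a, b = idx[:-1], idx[1:]
    ok = (a >= 0) & (b >= 0)
    di = np.bincount(a[ok] * 4 + b[ok], minlength=16).astype(np.float64)
    return mono, di.reshape(4, 4)


def _d2_from_counts(mono: np.ndarray, di: np.ndarray) -> tuple[float, float]:
    n = mono.sum()
    npairs = di.sum()
    if npairs < 1:
        raise ValueError("need at least one adjacent base pair")
    p = mono / n
    pij = di / npairs
    exp = np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pij > 0, pij * np.log2(pij / exp), 0.0)
    exact = max(0.0, float(terms.sum()))  # clip tiny negative rounding
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = np.where(exp > 0, (pij - exp) ** 2 / exp, 0.0)
    approx = float(quad.sum()) / (2.0 * np.log(2.0))
    return exact, approx


def d2_redundancy(
    seqs: str | Iterable[str], mode: str = "pooled"
) -> D2Result:
    """D2 of one or more sequences.

    ``mode="pooled"`` sums mono- and dinucleotide counts over all
    sequences before computing one D2 (adjacent pairs never straddle a
    sequence boundary); ``mode="per-sequence-mean"`` averages per-sequence
    D2 values over sequences that contain at least one pair.  The
    fluctuation bound always uses the total base count N.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    seqs = [s for s in seqs if s]
    if not seqs:
        raise ValueError("empty input")
    if mode not in ("pooled", "per-sequence-mean"):
        raise ValueError(f"unknown mode {mode!r}")
    monos, dis = zip(*(_counts(s) for s in seqs))
    mono = np.sum(monos, axis=0)
    di = np.sum(dis, axis=0)
    n = int(mono.sum())
    npairs = int(di.sum())
    if npairs < 1:
        raise ValueError("need at least one adjacent base pair")
    if mode == "pooled":
        exact, approx = _d2_from_counts(mono, di)
    else:
        vals = [
            _d2_from_counts(m, d) for m, d in zip(monos, dis) if d.sum() >= 1
        ]
        exact = float(np.mean([v[0] for v in vals]))
        approx = float(np.mean([v[1] for v in vals]))
    bound = d2_bound(n)
    return D2Result(
        d2=exact,
        n_bases=n,
        n_pairs_counted=npairs,
        fluctuation_bound=bound,
        significant=exact >= bound,
        mode=mode,
        d2_approx=approx,
    )


def d2_approx(seqs: str | Iterable[str], mode: str = "pooled") -> float:
    """Quadratic (chi-square style) approximation of D2; secondary output."""
    return d2_redundancy(seqs, mode=mode).d2_approx


def d2_bound(N: int) -> float:
    """99%-confidence fluctuation bound of D2 for N bases: 15.65 / N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return D2_BOUND_CONSTANT / N


def _histogram(values: Sequence[float], lo: float, hi: float, width: float) -> pd.DataFrame:
    edges = np.arange(lo, hi + width / 2, width)
    counts, _ = np.histogram(values, bins=edges)
    total = max(1, len(values))
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "fraction": counts / total,
        }
    )


def class_statistics(
    oms_list: Sequence[OptimalMatchedSegment],
    models: Sequence,
) -> dict[str, pd.DataFrame]:
    """Distribution report for a dataset of OMSs and its sequence classes.

    Returns histograms of OMS match rate (5% bins), intron-side OMS length
    (1 bp bins) and G+C (0.05 bins), plus a D2 table for the CDS, 5'UTR,
    3'UTR and OMS sequence classes in both pooled and per-sequence-mean
    modes.  The OMS class is the intron-side matched segments; empty OMSs
    are excluded from all distributions.
    """
    intron_by_id = {
        iid: seq for m in models for iid, _, seq in m.iter_pairs()
    }
    nonempty = [o for o in oms_list if not o.is_empty]
    oms_intron_seqs = [
        intron_by_id[o.aligned_id][o.intron_start - 1 : o.intron_end]
        for o in nonempty
        if o.aligned_id in intron_by_id
    ]
    rates = [match_rate(o) for o in nonempty]
    lengths = [o.intron_end - o.intron_start + 1 for o in nonempty]
    gcs = [gc_content(s) for s in oms_intron_seqs if s]

    out: dict[str, pd.DataFrame] = {
        "match_rate_hist": _histogram(rates, 0.0, 100.0, 5.0),
        "length_hist": _histogram(
            lengths, 0.5, (max(lengths) if lengths else 1) + 0.5, 1.0
        ),
        "gc_hist": _histogram(gcs, 0.0, 1.0, 0.05),
    }

    classes = {
        "CDS": [m.cds_seq for m in models],
        "5UTR": [m.utr5_seq for m in models if m.utr5_len > 1],
        "3UTR": [m.utr3_seq for m in models if m.utr3_len > 1],
        "OMS": [s for s in oms_intron_seqs if len(s) > 1],
    }
    rows = []
    for cname, seqs in classes.items():
        seqs = [s for s in seqs if s]
        if not seqs:
            continue
        for mode in ("pooled", "per-sequence-mean"):
            r = d2_redundancy(seqs, mode=mode)
            rows.append(
                (cname, mode, r.n_bases, r.d2, r.d2_approx, r.fluctuation_bound, r.significant)
            )
    out["d2_report"] = pd.DataFrame(
        rows,
        columns=["class", "mode", "n_bases", "d2", "d2_approx", "bound", "significant"],
    )
    return out
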