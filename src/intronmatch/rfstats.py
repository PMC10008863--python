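"""Matched-frequency statistics over normalized and site-anchored coordinates.

Every (mRNA, intron) pair contributes one optimal matched segment (OMS).
Positions on each mRNA are rescaled to 100 relative sites, each OMS is
turned into a 0/1 coverage vector over those sites, and averaging the
vectors over pairs gives the matched frequency F(k).  Dividing by the
dataset-average coverage <F> (the mean fractional OMS length) yields the
relative matched frequency RF(k); RF > 1 marks relative sites where
matched segments sit more often than average, and maximal runs of such
sites are the optimal matched regions (OMR).

Functional-site profiles repeat the calculation without length
normalization, in a +/-60 bp window anchored at the first base of the
start codon (AUG), the first base of the stop codon (UAA), or an
exon-exon junction (last base of the upstream exon), optionally split by
intron length class (short <= 80 bp, long > 80 bp).  The RF denominator
for a site window is the same <F> computed over the pair set contributing
to that window, so RF = 1 keeps its "average coverage" meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import OptimalMatchedSegment

__all__ = [
    "RFProfile",
    "SiteProfile",
    "normalize_site",
    "matched_score_vector",
    "matched_frequency",
    "average_matched_frequency",
    "relative_matched_frequency",
    "rf_profile_from_oms",
    "detect_omr",
    "site_profile",
    "compare_regions",
]

N_BINS = 100
SITE_TYPES = ("AUG", "UAA", "EE_first", "EE_middle", "EE_last")


def normalize_site(j: int, L: int) -> int:
    """Relative site k in 1..100 of the j-th base of a length-L sequence.

    k = 100*j/L when that is an integer, otherwise floor(100*j/L) + 1
    (equivalently ceil).  The last base always maps to 100.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 1 <= j <= L:
        raise ValueError(f"position j={j} outside 1..{L}")
    q, r = divmod(N_BINS * j, L)
    return q if r == 0 else q + 1


def matched_score_vector(oms: OptimalMatchedSegment, L: int) -> np.ndarray:
    """0/1 vector over the 100 relative sites covered by the OMS."""
    v = np.zeros(N_BINS, dtype=np.float64)
    if oms.is_empty:
        return v
    if not (1 <= oms.tested_start <= oms.tested_end <= L):
        raise ValueError("OMS coordinates outside the mRNA")
    ks = normalize_site(oms.tested_start, L)
    ke = normalize_site(oms.tested_end, L)
    v[ks - 1 : ke] = 1.0
    return v


def matched_frequency(vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise mean of per-pair score vectors: F(k) in [0, 1]."""
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValueError("need at least one score vector")
    return arr.mean(axis=0)


def average_matched_frequency(
    oms_list: Sequence[OptimalMatchedSegment],
    mrna_lengths: Sequence[int],
    normalized: bool = True,
) -> float:
    """<F> = mean over pairs of the fractional OMS length l_i / L_i.

    By default lengths are taken on the *normalized* coordinate axis
    (l_i = k_e - k_s + 1 relative sites, L_i = 100), the convention under
    which the mean of RF over the 100 bins is exactly 1.  With
    ``normalized=False`` the raw base-pair fraction on the un-normalized
    mRNA is used instead.
    """
    if len(oms_list) == 0:
        raise ValueError("need at least one pair")
    if len(oms_list) != len(mrna_lengths):
        raise ValueError("oms_list and mrna_lengths differ in length")
    fr = []
    for oms, L in zip(oms_list, mrna_lengths):
        if oms.is_empty:
            fr.append(0.0)
        elif normalized:
            ks = normalize_site(oms.tested_start, L)
            ke = normalize_site(oms.tested_end, L)
            fr.append((ke - ks + 1) / N_BINS)
        else:
            fr.append(oms.tested_length / L)
    return float(np.mean(fr))


@dataclass(frozen=True)
class RFProfile:
    """Relative matched frequency over 100 normalized relative sites."""

    bins: np.ndarray  # F(k), k = 1..100
    avg_f: float
    rf: np.ndarray  # F(k) / <F>
    n_pairs: int
    scheme_name: str = ""
    orientation: str = "complement"

    def __post_init__(self):
        if self.bins.shape != (N_BINS,) or self.rf.shape != (N_BINS,):
            raise ValueError("profiles must have exactly 100 bins")


def relative_matched_frequency(
    F: np.ndarray,
    avg_f: float,
    n_pairs: int = 0,
    scheme_name: str = "",
    orientation: str = "complement",
) -> RFProfile:
    """RF(k) = F(k) / <F>; rejects <F> = 0 (no matched segments at all)."""
    if avg_f <= 0:
        raise ValueError("no matched segments: <F> = 0, RF undefined")
    F = np.asarray(F, dtype=np.float64)
    return RFProfile(
        bins=F,
        avg_f=float(avg_f),
        rf=F / avg_f,
        n_pairs=n_pairs,
        scheme_name=scheme_name,
        orientation=orientation,
    )


def rf_profile_from_oms(
    oms_list: Sequence[OptimalMatchedSegment],
    mrna_lengths: Sequence[int],
    scheme_name: str = "",
    orientation: str = "complement",
) -> RFProfile:
    """Full normalized-coordinate pipeline for a list of pairs."""
    vectors = [matched_score_vector(o, L) for o, L in zip(oms_list, mrna_lengths)]
    F = matched_frequency(vectors)
    avg_f = average_matched_frequency(oms_list, mrna_lengths)
    return relative_matched_frequency(
        F, avg_f, n_pairs=len(oms_list), scheme_name=scheme_name, orientation=orientation
    )


def detect_omr(profile: RFProfile) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive bins with RF strictly > 1.

    Returns (start_bin, end_bin, peak_rf) per region, 1-based inclusive,
    in bin order.  RF exactly 1 does not open a region.
    """
    above = profile.rf > 1.0
    regions: list[tuple[int, int, float]] = []
    start = None
    for k in range(N_BINS):
        if above[k] and start is None:
            start = k
        elif not above[k] and start is not None:
            regions.append((start + 1, k, float(profile.rf[start:k].max())))
            start = None
    if start is not None:
        regions.append((start + 1, N_BINS, float(profile.rf[start:].max())))
    return regions


@dataclass(frozen=True)
class SiteProfile:
    """Un-normalized matched frequency around one functional site type."""

    site_type: str
    offsets: np.ndarray  # -window .. +window
    f: np.ndarray
    rf: np.ndarray
    intron_class: str
    n_pairs: int
    avg_f: float
    scheme_name: str = ""


def _site_positions(model, site_type: str, window: int) -> list[int]:
    """1-based mRNA positions of the anchors of ``site_type`` on a model."""
    if site_type == "AUG":
        anchors = [model.cds_start]
    elif site_type == "UAA":
        anchors = [model.cds_end - 2]  # first base of the stop codon
    elif site_type == "EE_first":
        anchors = [model.ee_junctions[0]] if model.ee_junctions else []
    elif site_type == "EE_last":
        anchors = [model.ee_junctions[-1]] if model.ee_junctions else []
    elif site_type == "EE_middle":
        anchors = list(model.ee_junctions[1:-1])
    else:
        raise ValueError(f"unknown site type {site_type!r}; choose from {SITE_TYPES}")
    # require the full window inside the mRNA (strict eligibility)
    return [a for a in anchors if a - window >= 1 and a + window <= model.length]


def site_profile(
    models: Sequence,
    oms_by_pair: dict[tuple[str, str], OptimalMatchedSegment],
    site_type: str,
    window: int = 60,
    intron_class: str = "all",
    long_short_threshold: int = 80,
    scheme_name: str = "",
) -> SiteProfile:
    """Matched-frequency profile in a +/-window around a functional site.

    ``oms_by_pair`` maps (mrna_id, intron_id) to the pair's OMS.  Each
    eligible (anchor, intron) combination contributes one coverage row;
    ``intron_class`` ("all" / "long" / "short") restricts the introns.
    For AUG/UAA the caller is expected to pass UTR-filtered models.
    """
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}; choose from {SITE_TYPES}")
    offsets = np.arange(-window, window + 1)
    width = 2 * window + 1
    cov_sum = np.zeros(width, dtype=np.float64)
    n_rows = 0
    frac_sum = 0.0
    n_pairs = 0
    for m in models:
        anchors = _site_positions(m, site_type, window)
        if not anchors:
            continue
        for iid, _, iseq in m.iter_pairs():
            if intron_class != "all":
                from .genemodels import classify_intron

                if classify_intron(len(iseq), long_short_threshold) != intron_class:
                    continue
            oms = oms_by_pair.get((m.transcript_id, iid))
            if oms is None:
                continue
            n_pairs += 1
            frac_sum += oms.tested_length / m.length
            for a in anchors:
                row = np.zeros(width)
                if not oms.is_empty:
                    lo = max(oms.tested_start, a - window)
                    hi = min(oms.tested_end, a + window)
                    if lo <= hi:
                        row[lo - (a - window) : hi - (a - window) + 1] = 1.0
                cov_sum += row
                n_rows += 1
    if n_rows == 0:
        raise ValueError(f"no eligible transcripts for site type {site_type!r}")
    f = cov_sum / n_rows
    avg_f = frac_sum / n_pairs
    if avg_f <= 0:
        raise ValueError("no matched segments: <F> = 0, RF undefined")
    return SiteProfile(
        site_type=site_type,
        offsets=offsets,
        f=f,
        rf=f / avg_f,
        intron_class=intron_class,
        n_pairs=n_rows,
        avg_f=avg_f,
        scheme_name=scheme_name,
    )


def compare_regions(
    values_a: Iterable[float], values_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sided Welch t-test between two sets of per-bin RF values.

    Descriptive (no multiple-testing correction).  Two identical
    zero-variance samples give (0.0, 1.0) with a warning rather than NaN.
    """
    a = np.asarray(list(values_a), dtype=np.float64)
    b = np.asarray(list(values_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        warnings.warn("degenerate zero-variance identical samples; p set to 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
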