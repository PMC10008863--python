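"""Synthetic gene-model generator with plantable intron-mRNA complementarity.

Emulates the structure of a single-isoform protein-coding dataset: each
gene has a handful of exons, introns of at least 40 bp drawn from a
long/short mixture around the 80 bp class threshold, and UTRs sized so
the site-window filters (5'UTR >= 50 bp, 3'UTR >= 80 bp) are satisfiable.
Background sequence is i.i.d. with a configurable G+C fraction; no splice
motifs, codon structure or evolutionary model is emulated.

Optionally, a fraction of (mRNA, intron) pairs receives a *planted*
complementary segment: a stretch of the mRNA inside a chosen region whose
complement (respecting the orientation convention in force) is copied
into the intron, with a configurable fraction of positions kept exactly
complementary.  A truth table records every planted segment so that
recovery by the alignment pipeline can be scored.  Identical seeds give
byte-identical FASTA/GFF3/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .align import complement
from .genemodels import TranscriptModel

__all__ = ["SimSpec", "simulate_transcript_models", "generate_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PLANT_REGIONS = ("5UTR", "CDS", "3UTR", "AUG", "UAA", "EE")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic dataset.

    Length ranges are inclusive.  ``plant_rate`` is the fraction of
    (mRNA, intron) pairs that receive a planted complementary segment in
    ``plant_region``; ``plant_identity`` is the fraction of planted intron
    positions forced complementary (the rest are randomized).  When
    ``plant_gc`` is a single number the planted mRNA stretch is generated
    de novo at that G+C; when it is a (low, high) pair, two competing
    segments — one at each G+C — are planted per selected pair; when None
    the existing mRNA content is used.
    """

    n_genes: int = 100
    exon_count: tuple[int, int] = (2, 6)
    exon_len: tuple[int, int] = (100, 300)
    intron_len_short: tuple[int, int] = (40, 80)
    intron_len_long: tuple[int, int] = (81, 400)
    p_long_intron: float = 0.5
    utr5_len: tuple[int, int] = (50, 120)
    utr3_len: tuple[int, int] = (80, 200)
    gc: float = 0.36  # roughly worm-like background composition
    plant_rate: float = 0.0
    plant_region: str = "3UTR"
    plant_len: tuple[int, int] = (25, 25)
    plant_identity: float = 1.0
    plant_gc: float | tuple[float, float] | None = None
    plant_window: int = 60  # half-width of AUG/UAA/EE plant regions
    orientation: str = "complement"
    flank: int = 50  # genomic flank on each side of every gene
    seed: int = 0

    def __post_init__(self):
        if self.plant_region not in PLANT_REGIONS:
            raise ValueError(
                f"unknown plant region {self.plant_region!r}; choose from {PLANT_REGIONS}"
            )
        for lo, hi in (
            self.exon_count,
            self.exon_len,
            self.intron_len_short,
            self.intron_len_long,
            self.utr5_len,
            self.utr3_len,
            self.plant_len,
        ):
            if not (1 <= lo <= hi):
                raise ValueError("length/count ranges must satisfy 1 <= low <= high")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if not 0.0 <= self.plant_identity <= 1.0:
            raise ValueError("plant_identity must be in [0, 1]")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return _BASES[rng.choice(4, size=n, p=p)]


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


_COMP = dict(zip(b"ACGT", b"TGCA"))


def _comp_bytes(arr: np.ndarray, reverse: bool) -> np.ndarray:
    out = np.array([_COMP[b] for b in arr], dtype=np.uint8)
    return out[::-1] if reverse else out


@dataclass
class _Gene:
    model: TranscriptModel
    exon_lens: list[int]  # transcript order
    intron_arrays: list[np.ndarray]
    mrna_array: np.ndarray
    strand: str


def _plant_region_interval(model: TranscriptModel, region: str, w: int, rng) -> tuple[int, int]:
    L = model.length
    if region == "5UTR":
        return 1, model.cds_start - 1
    if region == "CDS":
        return model.cds_start, model.cds_end
    if region == "3UTR":
        return model.cds_end + 1, L
    if region == "AUG":
        a = model.cds_start
    elif region == "UAA":
        a = model.cds_end - 2
    else:  # EE: a random junction
        if not model.ee_junctions:
            return 1, 0
        a = int(rng.choice(model.ee_junctions))
    return max(1, a - w), min(L, a + w)


def simulate_transcript_models(
    spec: SimSpec,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate the dataset in memory: (models, truth table).

    The truth table has one row per planted segment: mrna_id, intron_id,
    mrna_start, mrna_end, intron_start, intron_end (1-based inclusive),
    identity, gc (NaN when the plant copies existing mRNA content).
    Raises on an infeasible spec (plant longer than its target region).
    """
    genes = _simulate_genes(spec)
    truth = _plant(genes, spec)
    return [g.model for g in genes], truth


def _simulate_genes(spec: SimSpec) -> list[_Gene]:
    rng = np.random.default_rng(spec.seed)
    genes: list[_Gene] = []
    for gi in range(spec.n_genes):
        n_ex = _randint(rng, spec.exon_count)
        exon_lens = [_randint(rng, spec.exon_len) for _ in range(n_ex)]
        total = sum(exon_lens)
        u5 = _randint(rng, spec.utr5_len)
        u3 = _randint(rng, spec.utr3_len)
        cds_len = total - u5 - u3
        if cds_len < 9:  # pad the last exon so a minimal CDS fits
            exon_lens[-1] += 9 - cds_len
            total = sum(exon_lens)
            cds_len = 9
        u3 += cds_len % 3  # keep the CDS a multiple of 3
        cds_len -= cds_len % 3
        mrna = _random_seq(rng, total, spec.gc)
        cds_start = u5 + 1
        cds_end = u5 + cds_len
        mrna[cds_start - 1 : cds_start + 2] = np.frombuffer(b"ATG", dtype=np.uint8)
        mrna[cds_end - 3 : cds_end] = np.frombuffer(b"TAA", dtype=np.uint8)
        introns = []
        for _ in range(n_ex - 1):
            if rng.random() < spec.p_long_intron:
                ilen = _randint(rng, spec.intron_len_long)
            else:
                ilen = _randint(rng, spec.intron_len_short)
            introns.append(_random_seq(rng, ilen, spec.gc))
        junctions = tuple(np.cumsum(exon_lens[:-1]).tolist())
        strand = "+" if gi % 2 == 0 else "-"
        tid = f"t{gi + 1:05d}"
        model = TranscriptModel(
            gene_id=f"g{gi + 1:05d}",
            transcript_id=tid,
            strand=strand,
            mrna_seq=mrna.tobytes().decode(),
            cds_start=cds_start,
            cds_end=cds_end,
            ee_junctions=junctions,
            introns=tuple(i.tobytes().decode() for i in introns),
        )
        genes.append(_Gene(model, exon_lens, introns, mrna, strand))
    return genes


def _plant(genes: list[_Gene], spec: SimSpec) -> pd.DataFrame:
    rng = np.random.default_rng([spec.seed, 1])
    rows = []
    reverse = spec.orientation == "reverse_complement"
    gcs: tuple = ()
    if spec.plant_gc is not None:
        gcs = (
            tuple(spec.plant_gc)
            if isinstance(spec.plant_gc, (tuple, list))
            else (float(spec.plant_gc),)
        )
    for g in genes:
        model = g.model
        for ii, intron in enumerate(g.intron_arrays):
            if spec.plant_rate <= 0 or rng.random() >= spec.plant_rate:
                continue
            rlo, rhi = _plant_region_interval(model, spec.plant_region, spec.plant_window, rng)
            plant_gcs = list(gcs) if gcs else [None]
            rng.shuffle(plant_gcs)
            used_m: list[tuple[int, int]] = []
            used_i: list[tuple[int, int]] = []
            for pgc in plant_gcs:
                plen = _randint(rng, spec.plant_len)
                if rhi - rlo + 1 < plen:
                    raise ValueError(
                        f"plant length {plen} exceeds region "
                        f"{spec.plant_region} ({rhi - rlo + 1} bp) of {model.transcript_id}"
                    )
                if len(intron) < plen:
                    continue  # intron too short to carry this plant
                ms = _pick_interval(rng, rlo, rhi, plen, used_m)
                istart = _pick_interval(rng, 1, len(intron), plen, used_i)
                if ms is None or istart is None:
                    continue
                used_m.append((ms, ms + plen - 1))
                used_i.append((istart, istart + plen - 1))
                if pgc is not None:
                    seg = _random_seq(rng, plen, pgc)
                    g.mrna_array[ms - 1 : ms + plen - 1] = seg
                else:
                    seg = g.mrna_array[ms - 1 : ms + plen - 1].copy()
                iseg = _comp_bytes(seg, reverse)
                n_mut = int(round((1.0 - spec.plant_identity) * plen))
                if n_mut:
                    pos = rng.choice(plen, size=n_mut, replace=False)
                    for p in pos:
                        choices = _BASES[_BASES != iseg[p]]
                        iseg[p] = rng.choice(choices)
                intron[istart - 1 : istart + plen - 1] = iseg
                rows.append(
                    (
                        model.transcript_id,
                        model.intron_id(ii + 1),
                        ms,
                        ms + plen - 1,
                        istart,
                        istart + plen - 1,
                        spec.plant_identity,
                        np.nan if pgc is None else pgc,
                    )
                )
        # refresh the frozen model with mutated sequences
        g.model = replace(
            g.model,
            mrna_seq=g.mrna_array.tobytes().decode(),
            introns=tuple(i.tobytes().decode() for i in g.intron_arrays),
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mrna_id",
            "intron_id",
            "mrna_start",
            "mrna_end",
            "intron_start",
            "intron_end",
            "identity",
            "gc",
        ],
    )


def _pick_interval(rng, lo: int, hi: int, length: int, used: list[tuple[int, int]]):
    """Random start of a length-``length`` interval in [lo, hi] avoiding ``used``."""
    for _ in range(50):
        s = int(rng.integers(lo, hi - length + 2))
        e = s + length - 1
        if all(e < a or s > b for a, b in used):
            return s
    return None


def generate_dataset(spec: SimSpec, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, GFF3 annotation and truth TSV for ``spec``.

    Each gene occupies its own contig with ``spec.flank`` bp of random
    flank on each side; strands alternate so both orientations are
    exercised.  Returns the paths of the three files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _simulate_genes(spec)
    truth = _plant(genes, spec)
    frng = np.random.default_rng([spec.seed, 2])

    fa_path = outdir / "genome.fa"
    gff_path = outdir / "annotation.gff3"
    truth_path = outdir / "truth.tsv"

    with open(fa_path, "w") as fa, open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for gi, g in enumerate(genes):
            model = g.model
            contig = f"chr{gi + 1:05d}"
            pre_parts = []
            n_ex = len(g.exon_lens)
            mrna = g.model.mrna_seq
            t0 = 0
            for k in range(n_ex):
                pre_parts.append(mrna[t0 : t0 + g.exon_lens[k]])
                t0 += g.exon_lens[k]
                if k < n_ex - 1:
                    pre_parts.append(model.introns[k])
            pre = "".join(pre_parts)
            if g.strand == "-":
                pre = complement(pre, reverse=True)
            f5 = _random_seq(frng, spec.flank, spec.gc).tobytes().decode()
            f3 = _random_seq(frng, spec.flank, spec.gc).tobytes().decode()
            contig_seq = f5 + pre + f3
            fa.write(f">{contig}\n")
            for i in range(0, len(contig_seq), 70):
                fa.write(contig_seq[i : i + 70] + "\n")

            gstart = spec.flank + 1
            gend = spec.flank + len(pre)
            # transcript-order exon genomic spans
            spans_t = []
            pos = 0
            for k in range(n_ex):
                spans_t.append((pos + 1, pos + g.exon_lens[k]))  # pre-mRNA coords
                pos += g.exon_lens[k]
                if k < n_ex - 1:
                    pos += len(model.introns[k])
            if g.strand == "+":
                exon_spans = [(gstart + a - 1, gstart + b - 1) for a, b in spans_t]
            else:
                exon_spans = [(gend - b + 1, gend - a + 1) for a, b in spans_t]
            cds_spans = []
            t0 = 0
            for k, (a, b) in enumerate(spans_t):
                ex_lo, ex_hi = t0 + 1, t0 + g.exon_lens[k]
                lo = max(model.cds_start, ex_lo)
                hi = min(model.cds_end, ex_hi)
                if lo <= hi:
                    pa = a + (lo - ex_lo)
                    pb = a + (hi - ex_lo)
                    if g.strand == "+":
                        cds_spans.append((gstart + pa - 1, gstart + pb - 1))
                    else:
                        cds_spans.append((gend - pb + 1, gend - pa + 1))
                t0 = ex_hi
            gid, tid = model.gene_id, model.transcript_id
            gff.write(
                f"{contig}\tsim\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            gff.write(
                f"{contig}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            for n, (a, b) in enumerate(sorted(exon_spans), start=1):
                gff.write(
                    f"{contig}\tsim\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{n};Parent={tid}\n"
                )
            for n, (a, b) in enumerate(sorted(cds_spans), start=1):
                gff.write(
                    f"{contig}\tsim\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={tid}.cds{n};Parent={tid}\n"
                )
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"genome": fa_path, "gff3": gff_path, "truth": truth_path}
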