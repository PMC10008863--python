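"""Build the analysis dataset from a genome FASTA and GFF3 annotation.

Produces one :class:`TranscriptModel` per annotated mRNA: the spliced
mature mRNA sequence in transcript orientation, the CDS/UTR boundaries on
it, the exon-exon junction positions, and the ordered intron sequences.
Dataset filters follow the study design for single-isoform protein-coding
genes: genes with any intron shorter than 40 bp are dropped (the 5' splice
region and the pyrimidine-rich 3' splice region already occupy that
length), genes with more than one annotated isoform are dropped, and an
externally supplied ID list removes genes containing ncRNAs or repetitive
elements.  Introns are split into short (<= 80 bp) and long (> 80 bp)
classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .align import complement

log = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "parse_gene_models",
    "filter_dataset",
    "classify_intron",
    "utr_site_filter",
    "write_class_fastas",
    "pairing_manifest",
    "load_paired_fastas",
]

START_CODONS = ("ATG",)
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class TranscriptModel:
    """A single-isoform gene model in transcript orientation.

    ``mrna_seq`` is the spliced mature mRNA (5'->3').  ``cds_start`` and
    ``cds_end`` are 1-based inclusive positions of the CDS on ``mrna_seq``.
    ``ee_junctions`` holds, for each non-terminal exon, the 1-based mRNA
    position of its last base.  ``introns`` are the excised intron
    sequences, 5'->3' in transcript orientation.
    """

    gene_id: str
    transcript_id: str
    strand: str
    mrna_seq: str
    cds_start: int
    cds_end: int
    ee_junctions: tuple[int, ...]
    introns: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.mrna_seq)

    @property
    def utr5_len(self) -> int:
        return self.cds_start - 1

    @property
    def utr3_len(self) -> int:
        return len(self.mrna_seq) - self.cds_end

    @property
    def cds_seq(self) -> str:
        return self.mrna_seq[self.cds_start - 1 : self.cds_end]

    @property
    def utr5_seq(self) -> str:
        return self.mrna_seq[: self.cds_start - 1]

    @property
    def utr3_seq(self) -> str:
        return self.mrna_seq[self.cds_end :]

    def intron_id(self, index: int) -> str:
        """Stable intron identifier; ``index`` is 1-based transcript order."""
        return f"{self.transcript_id}_intron{index}"

    def iter_pairs(self) -> Iterable[tuple[str, int, str]]:
        """Yield (intron_id, intron_index, intron_seq) in transcript order."""
        for i, seq in enumerate(self.introns, start=1):
            yield self.intron_id(i), i, seq


def _revcomp(seq: str) -> str:
    return complement(seq, reverse=True)


def _transcript_coord(exons: Sequence[tuple[int, int]], g: int, strand: str) -> int:
    """Map a genomic position to a 1-based transcript coordinate."""
    offset = 0
    plus_pos = None
    for s, e in exons:
        if s <= g <= e:
            plus_pos = offset + (g - s + 1)
            break
        offset += e - s + 1
    if plus_pos is None:
        raise ValueError(f"genomic position {g} not covered by exons")
    total = sum(e - s + 1 for s, e in exons)
    return plus_pos if strand == "+" else total - plus_pos + 1


def parse_gene_models(gff3: str | Path, genome: str | Path) -> list[TranscriptModel]:
    """Parse gene models; malformed transcripts are rejected individually.

    A transcript is rejected (with a logged reason) when its contig is
    missing, an exon lies outside the contig, the CDS is not contained in
    the exons, or the CDS length is not a positive multiple of 3.  A
    non-standard start/stop codon only triggers a warning — the annotated
    CDS boundary stays the site anchor regardless.
    """
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = Fasta(str(genome))
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        gene_id = (mrna.attributes.get("Parent") or [tid])[0]
        try:
            models.append(_build_model(db, fasta, mrna, gene_id, tid))
        except ValueError as exc:
            log.warning("rejecting transcript %s: %s", tid, exc)
    return models


def _build_model(db, fasta, mrna, gene_id: str, tid: str) -> TranscriptModel:
    if mrna.seqid not in fasta:
        raise ValueError(f"contig {mrna.seqid} missing from genome FASTA")
    contig = fasta[mrna.seqid]
    clen = len(contig)
    strand = mrna.strand
    if strand not in "+-":
        raise ValueError(f"strand {strand!r} not supported")

    exons = sorted(
        (f.start, f.end) for f in db.children(mrna, featuretype="exon")
    )
    if not exons:
        raise ValueError("no exon features")
    for s, e in exons:
        if s < 1 or e > clen:
            raise ValueError(f"exon {s}-{e} outside contig (length {clen})")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError("overlapping exons")

    cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
    if not cds:
        raise ValueError("no CDS features")
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    for s, e in cds:
        if not any(es <= s and e <= ee for es, ee in exons):
            raise ValueError(f"CDS {s}-{e} not contained in an exon")
    cds_len = sum(e - s + 1 for s, e in cds)
    if cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} not a multiple of 3")

    exon_seqs = [str(contig[s - 1 : e]).upper() for s, e in exons]
    mrna_seq = "".join(exon_seqs)
    if strand == "-":
        mrna_seq = _revcomp(mrna_seq)

    five_prime = cds_lo if strand == "+" else cds_hi
    three_prime = cds_hi if strand == "+" else cds_lo
    cds_start = _transcript_coord(exons, five_prime, strand)
    cds_end = _transcript_coord(exons, three_prime, strand)

    start_codon = mrna_seq[cds_start - 1 : cds_start + 2]
    stop_codon = mrna_seq[cds_end - 3 : cds_end]
    if start_codon not in START_CODONS:
        log.warning("transcript %s: non-AUG start codon %s", tid, start_codon)
    if stop_codon not in STOP_CODONS:
        log.warning("transcript %s: non-standard stop codon %s", tid, stop_codon)

    lens = [e - s + 1 for s, e in exons]
    if strand == "-":
        lens = lens[::-1]
    junctions = []
    acc = 0
    for ln in lens[:-1]:
        acc += ln
        junctions.append(acc)

    intron_seqs = [
        str(contig[e1 : s2 - 1]).upper() for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]
    if strand == "-":
        intron_seqs = [_revcomp(s) for s in intron_seqs[::-1]]
    for iseq in intron_seqs:
        if len(iseq) < 1:
            raise ValueError("zero-length intron between adjacent exons")

    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=tid,
        strand=strand,
        mrna_seq=mrna_seq,
        cds_start=cds_start,
        cds_end=cds_end,
        ee_junctions=tuple(junctions),
        introns=tuple(intron_seqs),
    )


def classify_intron(length: int, threshold: int = 80) -> str:
    """Short iff length <= threshold (80 bp by default), else long."""
    if length < 1:
        raise ValueError("intron length must be >= 1")
    return "short" if length <= threshold else "long"


def filter_dataset(
    models: Iterable[TranscriptModel],
    min_intron: int = 40,
    single_isoform: bool = True,
    exclude_ids: Iterable[str] = (),
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Apply the dataset filters; returns (retained, report).

    Drops genes with more than one annotated mRNA (alternative splicing),
    genes with any intron shorter than ``min_intron`` (boundary inclusive:
    a 40 bp intron is retained), and genes in the external ``exclude_ids``
    list (ncRNA / repetitive-element genes, supplied by the user).  The
    report has one row per dropped gene: (gene_id, reason).
    """
    models = list(models)
    exclude = set(exclude_ids)
    per_gene: dict[str, int] = {}
    for m in models:
        per_gene[m.gene_id] = per_gene.get(m.gene_id, 0) + 1
    kept: list[TranscriptModel] = []
    rows: list[tuple[str, str]] = []
    seen_dropped: set[str] = set()

    def drop(gene_id: str, reason: str) -> None:
        if gene_id not in seen_dropped:
            rows.append((gene_id, reason))
            seen_dropped.add(gene_id)

    for m in models:
        if m.gene_id in exclude:
            drop(m.gene_id, "excluded_id")
        elif single_isoform and per_gene[m.gene_id] > 1:
            drop(m.gene_id, "multiple_isoforms")
        elif any(len(i) < min_intron for i in m.introns):
            drop(m.gene_id, f"intron<{min_intron}")
        else:
            kept.append(m)
    report = pd.DataFrame(rows, columns=["gene_id", "reason"])
    if not kept:
        log.warning("all %d transcripts filtered out", len(models))
    return kept, report


def utr_site_filter(
    models: Iterable[TranscriptModel], min_utr5: int = 50, min_utr3: int = 80
) -> list[TranscriptModel]:
    """Retain transcripts with 5'UTR >= 50 bp and 3'UTR >= 80 bp.

    Used only for the AUG/UAA site-window profiles, to avoid boundary
    effects; the whole-mRNA profile uses the unfiltered set.
    """
    return [m for m in models if m.utr5_len >= min_utr5 and m.utr3_len >= min_utr3]


def write_class_fastas(models: Sequence[TranscriptModel], outdir: str | Path) -> None:
    """Write mRNA / intron / CDS / UTR FASTA files for a model set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(name: str, records: Iterable[tuple[str, str]]) -> None:
        with open(outdir / name, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    dump("mrna.fa", ((m.transcript_id, m.mrna_seq) for m in models))
    dump(
        "introns.fa",
        ((iid, seq) for m in models for iid, _, seq in m.iter_pairs()),
    )
    dump("cds.fa", ((m.transcript_id, m.cds_seq) for m in models))
    dump(
        "utr5.fa",
        ((m.transcript_id, m.utr5_seq) for m in models if m.utr5_len > 0),
    )
    dump(
        "utr3.fa",
        ((m.transcript_id, m.utr3_seq) for m in models if m.utr3_len > 0),
    )


def pairing_manifest(
    models: Sequence[TranscriptModel], long_short_threshold: int = 80
) -> pd.DataFrame:
    """One row per (mRNA, intron) pair with the intron length class."""
    rows = []
    for m in models:
        for iid, idx, seq in m.iter_pairs():
            rows.append(
                (
                    m.transcript_id,
                    iid,
                    idx,
                    len(seq),
                    classify_intron(len(seq), long_short_threshold),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["mrna_id", "intron_id", "intron_index", "intron_length", "class"],
    )


def load_paired_fastas(
    mrna_fa: str | Path, intron_fa: str | Path, manifest: str | Path
) -> list[tuple[str, str, str, int, str]]:
    """Load pre-extracted pairs: (mrna_id, mrna_seq, intron_id, index, intron_seq).

    The manifest TSV must carry mrna_id / intron_id / intron_index columns
    (the format :func:`pairing_manifest` writes).
    """
    mrnas = {r.name: str(r[:]).upper() for r in Fasta(str(mrna_fa))}
    introns = {r.name: str(r[:]).upper() for r in Fasta(str(intron_fa))}
    man = pd.read_csv(manifest, sep="\t", comment="#")
    pairs = []
    for row in man.itertuples(index=False):
        if row.mrna_id not in mrnas:
            raise ValueError(f"mRNA {row.mrna_id} missing from {mrna_fa}")
        if row.intron_id not in introns:
            raise ValueError(f"intron {row.intron_id} missing from {intron_fa}")
        pairs.append(
            (
                row.mrna_id,
                mrnas[row.mrna_id],
                row.intron_id,
                int(row.intron_index),
                introns[row.intron_id],
            )
        )
    return pairs
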