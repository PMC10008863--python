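# Methods

## Problem and model

Post-spliced introns are free RNA species that may base-pair with their
own mature mRNA. `intronmatch` screens for such sequence-level
association: for each (mRNA, intron) pair, the intron is transformed into
its complementary sequence, the mRNA ("tested" sequence) is locally
aligned against it ("aligned" sequence), and the single best-scoring
segment — the optimal matched segment (OMS) — is mapped back onto the
original intron. A high-scoring OMS means the intron contains a stretch
whose complement resembles a stretch of the mRNA, i.e. a candidate
intron–mRNA duplex.

Two substitution schemes are implemented:

* **SW** — the standard EDNAFULL (NUC.4.4) nucleotide matrix (+5 match,
  −4 mismatch between canonical bases, published values for IUPAC
  ambiguity codes), loaded from Biopython's substitution-matrix
  collection.
* **BFE** — binding-free-energy weighting. In complemented space an
  identical A/T column corresponds to an A–T or T–A pair (two hydrogen
  bonds, +5) and an identical G/C column to a G–C or C–G pair (three
  hydrogen bonds, +6); any non-complementary pairing scores −4. The 5:6
  asymmetry reflects the ≈2:3 ratio of A–T to G–C pairing energies.
  Base stacking is not modelled. Columns involving N or any other
  ambiguity code score −4 under BFE, because the weighting is defined
  only for canonical pairs.

Both schemes use affine gaps with open = 50 and extend = 5, in the
EMBOSS `water` convention (a gap of length *g* costs 50 + (*g*−1)·5).
All scores are integers, so alignments are bit-reproducible.

### Aligner

The aligner is a Gotoh three-state Smith–Waterman (match state plus one
affine-gap state per sequence), JIT-compiled with numba. Determinism is
total: among equal-scoring cells the smallest tested (mRNA) end
coordinate wins, then the smallest aligned end coordinate; traceback
prefers diagonal over a gap in the aligned sequence over a gap in the
tested sequence; within a gap state, closing the gap is preferred on
score ties (keeping gaps short). Exactly one OMS is reported per pair;
co-optimal alternatives are discarded after tie-breaking. The empty
sentinel (score 0, zero length) is returned only when no positive
scoring column exists.

### Orientation

Whether the original study reversed the intron before complementing
(antiparallel duplex geometry) is not derivable from the method
description, which speaks only of "complementary sequences". The default
is therefore the literal plain complement; `reverse_complement` is a
first-class option, planting in the simulator follows whichever
convention is in force, and every output records the orientation used.

## RF statistics

Positions 1..L of each mRNA are mapped to 100 relative sites by
k = ⌈100·j/L⌉ (equivalently: 100·j/L when integral, else floor + 1), so
the last base always lands on site 100. Each OMS contributes a 0/1
coverage vector over the sites spanned by its mRNA interval; the
per-site mean over the N pairs is the matched frequency F(k), and the
relative matched frequency is RF(k) = F(k)/⟨F⟩.

⟨F⟩ is the mean fractional OMS length **on the normalized axis**,
(k_e − k_s + 1)/100 averaged over pairs. Under this convention the mean
of RF over the 100 sites is exactly 1, which is the normalization
identity the profile is designed around. The raw base-pair fraction
l/L on the un-normalized mRNA is available (`normalized=False`) but is
not the default: because a segment of l bases spans about 100·(l−1)/L + 1
discrete sites, the raw fraction runs systematically below the binned
coverage and would push mean RF above 1 for short segments.

Regions of consecutive sites with RF strictly greater than 1 are the
optimal matched regions (OMR).

**Site windows.** Profiles around functional sites use literal offsets
−60..+60 with no length normalization. Anchors: first base of the start
codon (AUG), first base of the stop codon (UAA), and the last base of
the upstream exon for exon–exon junctions, grouped into first / middle /
last junction. Transcripts must contain the full window (strict
eligibility) and, for AUG/UAA, pass the UTR filters (5′UTR ≥ 50 bp,
3′UTR ≥ 80 bp) to avoid boundary effects. The RF denominator for a
window is the same ⟨F⟩-style mean fractional coverage computed over the
pair set contributing to that window, so RF = 1 retains its "average
coverage" meaning; per-pair weighting is used throughout (a transcript
with five introns contributes five rows). Region comparisons use a
two-sided Welch t-test and are descriptive: no multiple-testing
correction is applied.

## Dataset construction and filters

Gene models are read from GFF3 + genome FASTA (gffutils in-memory DB,
pyfaidx) into transcript orientation. Filters: genes with more than one
annotated mRNA are dropped (no alternative splicing), genes with any
intron shorter than 40 bp are dropped (boundary inclusive — a 40 bp
intron is kept), and genes on a user-supplied ID list (ncRNA /
repetitive-element genes, which would need external databases to detect)
are dropped. Introns are classed short (≤ 80 bp) or long (> 80 bp). A
malformed transcript (missing contig, exon outside contig, CDS outside
exons, CDS length not a multiple of 3) is rejected individually with a
logged reason; a non-AUG start or non-standard stop codon is only a
warning, and the annotated CDS boundary remains the site anchor.

## D2 informational redundancy

D2 = Σᵢⱼ p̂ᵢⱼ log₂[p̂ᵢⱼ/(p̂ᵢ p̂ⱼ)] over the 16 dinucleotides, with
0·log 0 = 0; p̂ᵢ from mononucleotide counts over all N bases and p̂ᵢⱼ
from adjacent pairs counted within each sequence only. The exact
(mutual-information) form is primary and clipped at 0 against rounding;
the quadratic approximation Σ (p̂ᵢⱼ − p̂ᵢp̂ⱼ)²/(2 ln2 · p̂ᵢp̂ⱼ) is
emitted as a labelled secondary output (the two agree within 5% when
no p̂ᵢⱼ is rare). The 99%-confidence fluctuation bound for N bases is
15.65/N, consistent with the χ²(9 df) 0.99 quantile 21.67/(2 ln 2). For
class tables one D2 per class is computed from pooled counts (matching a
single-number-per-class report); the per-sequence mean is also emitted.
The OMS class uses the intron-side matched segments.

## CC-Random null

The composition-constrained null shuffles every mRNA and every intron by
a uniform Fisher–Yates permutation (exact mononucleotide multiset
preservation; dinucleotide-preserving shuffling is out of scope), then
reruns the alignment + RF pipeline. Each replicate draws its RNG stream
from (seed, replicate index); the default is 10 replicates. The null
profile is flat across the interior of the 100 sites, with per-bin
Monte-Carlo mean and standard error reported.

**Known edge behaviour.** The terminal relative sites (roughly bins 1–2
and 99–100) sit systematically below RF = 1 even under the null: a
matched segment of length l can cover an interior base from ~l start
positions but the first/last bases from far fewer, so coverage — real or
shuffled — is depressed at the profile edges. This is placement
geometry, not sequence structure; it does not shrink with more pairs or
replicates, and it affects real and null profiles alike (their
comparison is therefore unaffected). Flatness claims about the null hold
for the interior bins only.

## Synthetic data generator

The generator emulates single-isoform protein-coding gene structure:
2–6 exons of 100–300 bp; introns ≥ 40 bp drawn from an equal mixture of
short (40–80 bp) and long (81–400 bp) uniform ranges around the 80 bp
class threshold; 5′UTRs of 50–120 bp and 3′UTRs of 80–200 bp so the
site-window filters are satisfiable; i.i.d. background at G+C = 0.36
(roughly worm-like composition). A start ATG and stop TAA are forced at
the CDS boundaries; splice-site motifs, codon structure and evolutionary
models are deliberately not emulated. Genes alternate strands, one
contig per gene with 50 bp flanks, and identical seeds give
byte-identical FASTA/GFF3/TSV.

Planting writes a complementary copy of an mRNA stretch (region
selectable: UTRs, CDS, or ±60 bp site windows) into the intron at the
orientation convention in force, with a configurable fraction of
positions kept exactly complementary. With `plant_gc` set, the mRNA
stretch is generated de novo at that G+C (a (low, high) pair plants two
competing segments per pair, which is how the BFE-vs-SW G+C preference
is exercised: both compete at equal length and identity, SW is
indifferent while BFE prefers the G+C-rich one).

Because the background is i.i.d. and plants are perfect complements,
passing tests demonstrate the pipeline's mechanics — filter arithmetic,
coordinate mapping, profile normalization, signal recovery, null
flatness — not biological claims about real genomes: real introns carry
splice motifs, repeats and compositional heterogeneity that the
generator does not model, and real effect sizes are far smaller than
identity-1.0 plants.

A note on recovery granularity: a recovered OMS almost always covers the
planted interval but can extend a few bases past its boundaries through
chance positive-scoring flank matches, so recovery is scored as coverage
of the plant (and OMR-level overlap on the profile), not as exact
interval equality.

## Problem sizes and numerical choices

Default analysis sizes used by the test-suite and the reproduction
script: 200-pair datasets for the normalization identity, ~500-pair
datasets for planted-peak recovery and the null band (10 replicates),
5,000 × 2,000-base Monte-Carlo for the D2 bound, one 10⁶-base sequence
for the D2 limit, and 1,000 random pairs of length ≤ 12 for exhaustive
aligner verification (at that size the 50-point gap-open cost provably
exceeds any gapped gain, so ungapped enumeration is an exact oracle).
Coordinates are 0-based half-open internally and 1-based inclusive in
all emitted tables; U is folded into T on input; all randomness derives
from a single top-level seed via numpy `SeedSequence` streams.
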