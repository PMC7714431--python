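"""Strand-aware assignment of selected reads to repeat families and
fold-enrichment relative to genomic abundance.

A read placement (an already-mapped read: chrom, 0-based half-open
interval, strand relative to the reference) is assigned to a repeat
family when its midpoint lies inside one of the family's annotated
intervals; the read strand relative to the repeat's annotated strand
decides sense versus antisense. Fold enrichment of a family is the
dominant strand's share of all placed reads divided by that strand's
share of the genome's strand space (reads come from both strands, so
the dominant strand of a family covers family_bp of 2*genome_bp
strand-bases):

    fold = (dominant_count / total_reads) / (family_bp / (2 * genome_bp))

so uniformly sampled reads with uniform strands give fold ~ 1 for
every family; a plain base-pair-fraction denominator is available as
an option. The per-base-pair denominator is used (rather than a
per-locus count)
because locus counts are ill-defined when source and reference genomes
differ, whereas the annotated base fraction is well-defined everywhere.
Read mapping itself is out of scope: placements come from the simulator
(ground truth) or any external aligner as a 6-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .ctd_bias import BackgroundModel
from .seqcore import ANTISENSE, NucSeq, RepeatAnnotation, SENSE


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped read: 0-based half-open interval, strand vs reference."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.read_id!r}: invalid interval {self.start}-{self.end}")
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"{self.read_id!r}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FamilyCounts:
    """Per-family sense/antisense read tallies plus genomic abundance."""

    family: str
    sense_count: int = 0
    antisense_count: int = 0
    genomic_bp: int = 0
    genome_bp: int = 0

    def __post_init__(self) -> None:
        if self.genomic_bp > self.genome_bp:
            raise ValueError(f"{self.family!r}: genomic_bp exceeds genome_bp")


@dataclass(frozen=True)
class EnrichmentRecord:
    family: str
    dominant_strand: str
    dominant_count: int
    fold_enrichment: float


@dataclass(frozen=True)
class ContigStack:
    """A fixed-width genomic window with the reads whose midpoints it holds."""

    chrom: str
    window_start: int
    window_end: int
    read_count: int


@dataclass
class AssignmentResult:
    """Family counts plus the tally of reads hitting no annotated interval."""

    family_counts: list[FamilyCounts] = field(default_factory=list)
    unannotated: int = 0

    def by_family(self) -> dict[str, FamilyCounts]:
        return {fc.family: fc for fc in self.family_counts}

    @property
    def total_assigned(self) -> int:
        return sum(fc.sense_count + fc.antisense_count for fc in self.family_counts)


def assign_reads(
    placements: list[ReadPlacement],
    annot: RepeatAnnotation,
    chrom_lengths: dict[str, int],
) -> AssignmentResult:
    """Assign each read to at most one repeat family by its midpoint.

    A read whose midpoint falls in an annotated interval counts as
    sense when the read strand equals the repeat's annotated strand,
    antisense otherwise. If intervals of several families overlap the
    midpoint, the interval with the smallest start (then lexicographic
    family name) wins, so every read is counted exactly once and
    sense + antisense + unannotated == total. Unknown chromosomes in
    placements raise an error naming the offender.
    """
    genome_bp = sum(chrom_lengths.values())
    trees: dict[str, IntervalTree] = {}
    for r in annot:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"annotation on unknown chromosome {r.chrom!r}")
        if r.end > chrom_lengths[r.chrom]:
            raise ValueError(f"interval {r.chrom}:{r.start}-{r.end} exceeds chromosome length")
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    counts: dict[str, FamilyCounts] = {
        fam: FamilyCounts(family=fam, genomic_bp=bp, genome_bp=genome_bp)
        for fam, bp in annot.family_bp().items()
    }
    unannotated = 0
    for p in placements:
        if p.chrom not in chrom_lengths:
            raise ValueError(f"placement {p.read_id!r} on unknown chromosome {p.chrom!r}")
        tree = trees.get(p.chrom)
        hits = sorted(tree[p.midpoint], key=lambda iv: (iv.begin, iv.data.family)) if tree else []
        if not hits:
            unannotated += 1
            continue
        rec = hits[0].data
        fc = counts[rec.family]
        if p.strand == rec.strand:
            fc.sense_count += 1
        else:
            fc.antisense_count += 1
    return AssignmentResult(
        family_counts=sorted(counts.values(), key=lambda fc: fc.family),
        unannotated=unannotated,
    )


def fold_enrichment(
    fc: FamilyCounts, total_reads: int, strand_aware_abundance: bool = True
) -> EnrichmentRecord:
    """Dominant-strand read share over the family's genomic abundance share.

    With ``strand_aware_abundance`` (default) the denominator is the
    family's share of strand space, ``family_bp / (2 * genome_bp)``:
    reads are sampled from both genome strands, and the dominant strand
    of a family covers family_bp of the 2*genome_bp strand-bases, so
    uniformly placed reads with uniform strands give fold -> 1 for
    every family (the normalisation identity). With it off the
    denominator is the plain base-pair fraction ``family_bp /
    genome_bp`` (uniform placement then converges to 0.5, since the
    dominant strand holds only half the family's reads). Strand ties
    break toward sense.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if fc.genomic_bp <= 0:
        raise ValueError(f"family {fc.family!r} absent from annotation (genomic_bp = 0)")
    if fc.sense_count >= fc.antisense_count:
        dominant_strand, dominant = SENSE, fc.sense_count
    else:
        dominant_strand, dominant = ANTISENSE, fc.antisense_count
    denom_bp = fc.genome_bp * 2 if strand_aware_abundance else fc.genome_bp
    fold = (dominant / total_reads) / (fc.genomic_bp / denom_bp)
    return EnrichmentRecord(
        family=fc.family,
        dominant_strand=dominant_strand,
        dominant_count=dominant,
        fold_enrichment=fold,
    )


def contig_stacks(
    placements: list[ReadPlacement],
    chrom_lengths: dict[str, int],
    window: int = 400,
) -> list[ContigStack]:
    """Tile each chromosome with fixed windows and stack reads by midpoint.

    Windows tile from 0; the last window is truncated at the chromosome
    end; windows with zero reads are omitted. The counts over all
    returned windows sum to the number of placed reads.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tallies: dict[tuple[str, int], int] = {}
    for p in placements:
        if p.chrom not in chrom_lengths:
            raise ValueError(f"placement {p.read_id!r} on unknown chromosome {p.chrom!r}")
        w = p.midpoint // window
        tallies[(p.chrom, w)] = tallies.get((p.chrom, w), 0) + 1
    out = []
    for (chrom, w), count in sorted(tallies.items()):
        start = w * window
        end = min(start + window, chrom_lengths[chrom])
        out.append(ContigStack(chrom=chrom, window_start=start, window_end=end, read_count=count))
    return out


@dataclass(frozen=True)
class CaRichnessResult:
    observed_fraction: float
    z: float
    p_empirical: float
    ca_dinucleotide_freq: float
    n_perm: int


def ca_richness(
    seqs: list[NucSeq],
    bg: BackgroundModel | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CaRichnessResult:
    """Are the sequences richer in C+A bases than background chance?

    Observed statistic: pooled fraction of C and A over all sequences.
    Null: same-length i.i.d. sequences from the background model; for
    the pooled fraction this is exactly Binomial(total_length, p_C+p_A)
    scaled by total length, which is sampled directly. Upper-tail
    empirical p = (m+1)/(n+1) with m = #{null >= observed}. The CA
    dinucleotide frequency (overlapping count / (length-1), pooled) is
    reported as a secondary descriptive statistic.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    bg = bg or BackgroundModel.human_genome()
    total_len = sum(len(s) for s in seqs)
    ca_bases = sum(s.seq.count("C") + s.seq.count("A") for s in seqs)
    observed = ca_bases / total_len
    ca_dinuc = sum(_overlapping_count(s.seq, "CA") for s in seqs)
    dinuc_positions = sum(max(len(s) - 1, 0) for s in seqs)
    p_ca = bg.base_freqs[0] + bg.base_freqs[1]  # A + C
    rng = np.random.default_rng(seed)
    null = rng.binomial(total_len, p_ca, size=n_perm) / total_len
    m = int(np.sum(null >= observed))
    sd = float(null.std(ddof=1))
    z = (observed - float(null.mean())) / sd if sd > 0 else float("nan")
    return CaRichnessResult(
        observed_fraction=observed,
        z=z,
        p_empirical=(m + 1) / (n_perm + 1),
        ca_dinucleotide_freq=ca_dinuc / dinuc_positions if dinuc_positions else 0.0,
        n_perm=n_perm,
    )


def _overlapping_count(s: str, motif: str) -> int:
    count = start = 0
    while True:
        i = s.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


# ---------------------------------------------------------------------------
# placement TSV I/O (read_id, chrom, start, end, strand, family-or-.)
# ---------------------------------------------------------------------------

def write_placements(
    placements: list[ReadPlacement],
    path: str | Path,
    families: dict[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tfamily\n")
        for p in placements:
            fam = (families or {}).get(p.read_id, ".")
            fh.write(f"{p.read_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.strand}\t{fam}\n")


def read_placements(path: str | Path) -> list[ReadPlacement]:
    out: list[ReadPlacement] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}:1: missing placement header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            read_id, chrom, start, end, strand = fields[:5]
            try:
                out.append(
                    ReadPlacement(
                        read_id=read_id, chrom=chrom,
                        start=int(start), end=int(end), strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out
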