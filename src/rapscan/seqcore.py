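"""Sequence data model, genetic-code translation, composition profiles and I/O.

Everything downstream (alignment, composition statistics, enrichment
counting, the simulator) works on the two sequence types defined here.
Nucleotide sequences are held as DNA internally: RNA input (``U``) is
mapped to ``T`` on ingest, because the SELEX library and the reference
genome are both handled as DNA and the selected RNAs map back onto it.
Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("rapscan")

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

#: canonical index order for the 20 standard amino acids
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

SENSE = "+"
ANTISENSE = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over {A,C,G,T,N} with a strand label.

    RNA input is accepted and converted to DNA (U -> T); lower case is
    folded to upper case. ``strand`` is '+' (sense, default) or '-'.
    """

    id: str
    seq: str
    strand: str = SENSE

    def __post_init__(self) -> None:
        s = self.seq.upper().replace("U", "T")
        object.__setattr__(self, "seq", s)
        if not s:
            raise ValueError(f"{self.id!r}: empty nucleotide sequence")
        bad = set(s) - NUC_ALPHABET
        if bad:
            raise ValueError(f"{self.id!r}: invalid nucleotide(s) {sorted(bad)}")
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"{self.id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSeq:
    """A named amino-acid sequence (20 standard letters, '*' stop, 'X' unknown)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id!r}: invalid amino-acid letter(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


class GeneticCode:
    """The universal (standard) genetic code over DNA codons.

    ``table`` maps each of the 64 codons to an amino-acid letter or '*';
    ``codon_multiplicity`` maps each amino acid to its number of sense
    codons (these multiplicities are what the composition statistic
    normalises by).
    """

    def __init__(self) -> None:
        std = CodonTable.unambiguous_dna_by_id[1]
        self.table: dict[str, str] = dict(std.forward_table)
        for stop in std.stop_codons:
            self.table[stop] = "*"
        if len(self.table) != 64:
            raise AssertionError("genetic code must cover all 64 codons")
        self.stop_codons = tuple(sorted(std.stop_codons))
        mult: dict[str, int] = {aa: 0 for aa in AA_ORDER}
        for codon, aa in self.table.items():
            if aa != "*":
                mult[aa] += 1
        if sum(mult.values()) != 61 or len(self.stop_codons) != 3:
            raise AssertionError("expected 61 sense codons and 3 stops")
        self.codon_multiplicity: dict[str, int] = mult

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.table.items() if aa != "*")


#: module-level singleton; the code never changes
STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class RepeatInterval:
    """One annotated repeat locus: 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    family: str
    strand: str = SENSE

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RepeatAnnotation:
    """A collection of repeat intervals labelled by family and strand.

    Intervals of one family on one strand may not overlap each other
    (enforced); different families may in principle overlap.
    """

    records: list[RepeatInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        for r in self.records:
            seen.setdefault((r.chrom, r.family, r.strand), []).append((r.start, r.end))
        for key, ivals in seen.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping intervals for family {key[1]!r} on "
                        f"{key[0]}({key[2]}) at {s1}-{e1} / {s2}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def families(self) -> list[str]:
        return sorted({r.family for r in self.records})

    def family_bp(self) -> dict[str, int]:
        """Total annotated bases per family (both strands pooled)."""
        out: dict[str, int] = {}
        for r in self.records:
            out[r.family] = out.get(r.family, 0) + len(r)
        return out


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate(seq: NucSeq, frame: int = 0, code: GeneticCode | None = None) -> ProteinSeq:
    """Translate one reading frame of ``seq`` (5'->3' of the given strand).

    The trailing partial codon is dropped. Stop codons are emitted as
    '*'; codons containing 'N' are emitted as 'X' and tallied in a
    warning (both are excluded from every downstream frequency vector).
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(seq) - frame < 3:
        raise ValueError(f"{seq.id!r}: too short to translate frame {frame}")
    code = code or STANDARD_CODE
    aas = []
    n_unknown = 0
    s = seq.seq
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            aas.append("X")
            n_unknown += 1
        else:
            aas.append(code.table[codon])
    if n_unknown:
        logger.warning(
            "%s frame %d: %d codon(s) contained N, emitted as X", seq.id, frame, n_unknown
        )
    return ProteinSeq(id=f"{seq.id}|frame{frame}", seq="".join(aas))


def translate_three_frames(seq: NucSeq, code: GeneticCode | None = None) -> list[ProteinSeq]:
    """Translations at frames 0, 1 and 2 of the given strand only.

    No reverse complement is taken: the frames of interest are 5'->3'
    on the selected RNA itself.
    """
    if len(seq) < 5:
        raise ValueError(f"{seq.id!r}: too short for three frames (need >= 5 nt)")
    return [translate(seq, frame, code) for frame in (0, 1, 2)]


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Reverse complement; N maps to N, the strand label is flipped."""
    rc = seq.seq.translate(_COMPLEMENT)[::-1]
    flipped = ANTISENSE if seq.strand == SENSE else SENSE
    return NucSeq(id=seq.id, seq=rc, strand=flipped)


def nucleobase_density_profile(seq: NucSeq, base: str, window: int) -> np.ndarray:
    """Sliding-window fraction of ``base``, one value per window start.

    Returns ``len(seq) - window + 1`` values in [0, 1].
    """
    if base not in "ACGT":
        raise ValueError("base must be one of A, C, G, T")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    hits = np.frombuffer(seq.seq.encode(), dtype=np.uint8) == ord(base)
    cum = np.concatenate([[0], np.cumsum(hits)])
    return (cum[window:] - cum[:-window]) / window


# ---------------------------------------------------------------------------
# I/O: FASTA, BED6, generic TSV tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "nuc") -> list[NucSeq] | list[ProteinSeq]:
    """Read a multi-record FASTA into NucSeq (``kind='nuc'``) or ProteinSeq.

    Record ids must be unique within the file. An empty file yields an
    empty list.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record ids")
    if kind == "nuc":
        return [NucSeq(id=r.id, seq=str(r.seq)) for r in records]
    if kind == "protein":
        return [ProteinSeq(id=r.id, seq=str(r.seq)) for r in records]
    raise ValueError("kind must be 'nuc' or 'protein'")


def write_fasta(records: Iterable[NucSeq | ProteinSeq], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def read_bed(path: str | Path) -> RepeatAnnotation:
    """Read a BED6 repeat annotation (name column = repeat family).

    0-based half-open, strand in column 6. Malformed lines raise an
    error naming the line number; an empty file yields an empty
    annotation.
    """
    records: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, family, _score, strand = fields[:6]
            try:
                interval = RepeatInterval(
                    chrom=chrom, start=int(start), end=int(end),
                    family=family, strand=strand,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(interval)
    return RepeatAnnotation(records=records)


def write_bed(annot: RepeatAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in annot:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t.\t{r.strand}\n")


def write_table(rows: Sequence[dict], path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write dict rows as a tab-separated table with a header line.

    Floats are rendered with fixed precision so repeated runs are
    byte-identical.
    """
    if not rows:
        raise ValueError("cannot write an empty table (no header known)")
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            out = []
            for c in cols:
                v = row[c]
                if isinstance(v, float):
                    out.append(float_fmt % v)
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_table(path: str | Path) -> list[dict]:
    """Read a header-bearing TSV back into dict rows (values as strings)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]
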