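"""Synthetic genomic-SELEX data with full ground truth.

Emulates the statistical structure of the experiment end to end: an
i.i.d. background "genome" with configurable mononucleotide
frequencies, planted repeat families on both strands (one builder emits
tandem reverse-translations of the Pol II CTD heptad YSPTSPS, the
ACRO1-like case — seven noiseless heptads make the 147-nt unit whose
frame-0 translation is exact heptads), and an affinity-weighted read
sampler standing in for the selection cycles: a read's midpoint is
drawn with probability proportional to the local affinity weight
(family weight inside a planted interval, 1 elsewhere), its length
uniform over the library range, its strand uniform, with optional
per-base substitution noise. Everything is a pure function of
(config, seed): identical inputs give byte-identical outputs.

The affinity weight of a family directly fixes the expected fold
enrichment: with per-base weight w on a family covering fraction f of
the genome, the expected fraction of read midpoints inside the family
is w*f / (w*f + (1-f)), half of which lands on each strand (strands are
sampled uniformly), and dividing the per-strand share by f gives the
analytic per-strand fold (`expected_fold`). A single selection round
with weight w stands in for the multi-cycle protocol; compounding over
``rounds`` (effective weight w**rounds) is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import CTD_HEPTAD
from .ctd_bias import BackgroundModel
from .enrichment import ReadPlacement
from .seqcore import (
    ANTISENSE,
    NucSeq,
    RepeatAnnotation,
    RepeatInterval,
    SENSE,
    STANDARD_CODE,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: synonymous codons per amino acid, sorted for determinism
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(STANDARD_CODE.table.items()):
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class FamilySpec:
    """One planted repeat family.

    builder: 'random' (background-composition unit), 'ctd_reverse_translation'
    (tandem reverse-translated YSPTSPS heptads, codons uniform per amino
    acid), or 'simple_repeat' (tiled ``motif``). strand_rule: 'sense',
    'antisense', or 'both' (each copy's strand drawn uniformly).
    """

    name: str
    unit_length: int
    copies: int
    builder: str = "random"
    motif: str | None = None
    strand_rule: str = "both"
    affinity_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copies < 1:
            raise ValueError(f"{self.name!r}: unit_length and copies must be >= 1")
        if self.builder not in ("random", "ctd_reverse_translation", "simple_repeat"):
            raise ValueError(f"{self.name!r}: unknown builder {self.builder!r}")
        if self.builder == "simple_repeat" and not self.motif:
            raise ValueError(f"{self.name!r}: simple_repeat needs a motif")
        if self.strand_rule not in ("sense", "antisense", "both"):
            raise ValueError(f"{self.name!r}: unknown strand rule {self.strand_rule!r}")
        if self.affinity_weight < 0:
            raise ValueError(f"{self.name!r}: affinity weight must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation scenario: genome, planted families, read pool."""

    genome_length: int = 100_000
    bg: BackgroundModel = field(default_factory=BackgroundModel.human_genome)
    families: tuple[FamilySpec, ...] = ()
    read_count: int = 10_000
    read_length_range: tuple[int, int] = (30, 400)
    noise: float = 0.0
    rounds: int = 1
    seed: int = 0
    chrom: str = "chr_sim"

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if not (1 <= lo <= hi <= self.genome_length):
            raise ValueError("read_length_range must satisfy 1 <= lo <= hi <= genome_length")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be a probability")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        planted = sum(f.unit_length * f.copies for f in self.families)
        if planted > self.genome_length:
            raise ValueError("planted repeat copies exceed genome length")


@dataclass
class GroundTruth:
    """What was actually planted and sampled, for validation."""

    annotation: RepeatAnnotation
    affinity_map: dict[str, float]
    placements: list[ReadPlacement] = field(default_factory=list)
    read_families: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# unit builders
# ---------------------------------------------------------------------------

def _random_bases(n: int, bg: BackgroundModel, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(bg.as_array())
    idx = np.searchsorted(cum, rng.random(n))
    return _BASES[np.clip(idx, 0, 3)]


def reverse_translate_ctd(n_codons: int, rng: np.random.Generator) -> str:
    """Reverse-translate tandem YSPTSPS heptads, codons uniform per amino acid."""
    out = []
    for i in range(n_codons):
        aa = CTD_HEPTAD[i % len(CTD_HEPTAD)]
        codons = _CODONS_BY_AA[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _build_unit(spec: FamilySpec, bg: BackgroundModel, rng: np.random.Generator) -> str:
    if spec.builder == "simple_repeat":
        reps = -(-spec.unit_length // len(spec.motif))  # ceil
        return (spec.motif * reps)[: spec.unit_length]
    if spec.builder == "ctd_reverse_translation":
        n_codons = -(-spec.unit_length // 3)
        return reverse_translate_ctd(n_codons, rng)[: spec.unit_length]
    return _random_bases(spec.unit_length, bg, rng).tobytes().decode()


def _apply_noise(seq: str, noise: float, rng: np.random.Generator) -> str:
    """Per-base substitution to a uniformly chosen different base."""
    if noise <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < noise
    if hit.any():
        # offset 1..3 from the current base index guarantees a change
        base_idx = np.searchsorted(_BASES, arr[hit])
        new_idx = (base_idx + rng.integers(1, 4, size=int(hit.sum()))) % 4
        arr[hit] = _BASES[new_idx]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(cfg: SimConfig) -> tuple[NucSeq, RepeatAnnotation, GroundTruth]:
    """Background genome with planted, non-overlapping repeat units.

    Each copy of each family is an interval annotated with the family
    name and its placement strand; an antisense copy is inserted as the
    unit's reverse complement, so extracting the interval and
    reverse-complementing recovers the unit (up to noise). Raises if
    the copies cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = _random_bases(cfg.genome_length, cfg.bg, rng)
    occupied: list[tuple[int, int]] = []
    records: list[RepeatInterval] = []
    for spec in cfg.families:
        unit = _build_unit(spec, cfg.bg, rng)
        for copy_i in range(spec.copies):
            placed = False
            for _attempt in range(1000):
                start = int(rng.integers(0, cfg.genome_length - spec.unit_length + 1))
                end = start + spec.unit_length
                if all(end <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place copy {copy_i} of family {spec.name!r} without overlap"
                )
            occupied.append((start, end))
            if spec.strand_rule == "both":
                strand = SENSE if rng.random() < 0.5 else ANTISENSE
            else:
                strand = SENSE if spec.strand_rule == "sense" else ANTISENSE
            inserted = _apply_noise(unit, cfg.noise, rng)
            if strand == ANTISENSE:
                inserted = reverse_complement(NucSeq(id="u", seq=inserted)).seq
            genome[start:end] = np.frombuffer(inserted.encode(), dtype=np.uint8)
            records.append(
                RepeatInterval(chrom=cfg.chrom, start=start, end=end,
                               family=spec.name, strand=strand)
            )
    annotation = RepeatAnnotation(records=sorted(records, key=lambda r: r.start))
    truth = GroundTruth(
        annotation=annotation,
        affinity_map={spec.name: spec.affinity_weight for spec in cfg.families},
    )
    return NucSeq(id=cfg.chrom, seq=genome.tobytes().decode()), annotation, truth


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _position_weights(cfg: SimConfig, truth: GroundTruth) -> np.ndarray:
    w = np.ones(cfg.genome_length)
    for rec in truth.annotation:
        weight = truth.affinity_map.get(rec.family, 1.0) ** cfg.rounds
        w[rec.start : rec.end] = weight
    return w


def expected_fold(cfg: SimConfig, truth: GroundTruth, family: str) -> float:
    """Analytic per-strand fold enrichment implied by the sampling rule.

    P(midpoint in family) = sum of weights over family bases / total
    weight; a uniform strand coin halves it per strand; dividing the
    per-strand share by the family's strand-space fraction
    (family_bp / (2 * genome_bp)) gives the fold the counting pipeline
    (strand-aware default) should recover.
    """
    w = _position_weights(cfg, truth)
    fam_bp = sum(len(r) for r in truth.annotation if r.family == family)
    if fam_bp == 0:
        raise ValueError(f"family {family!r} not planted")
    fam_weight = sum(
        w[r.start : r.end].sum() for r in truth.annotation if r.family == family
    )
    p_family = fam_weight / w.sum()
    per_strand_share = p_family / 2.0
    return per_strand_share / (fam_bp / (2 * cfg.genome_length))


def sample_reads(
    genome: NucSeq, truth: GroundTruth, cfg: SimConfig
) -> tuple[list[NucSeq], list[ReadPlacement]]:
    """Affinity-weighted read pool with ground-truth placements.

    Midpoints are drawn proportional to per-base affinity weight, read
    lengths uniformly over the library range, strands uniformly; the
    read sequence is the (possibly reverse-complemented) genomic
    substring with per-base substitution noise. The true placement of
    every read is recorded; the emitted read order is deterministic.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    w = _position_weights(cfg, truth)
    p = w / w.sum()
    mids = rng.choice(cfg.genome_length, size=cfg.read_count, p=p)
    lo, hi = cfg.read_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.read_count)
    strands = rng.random(cfg.read_count) < 0.5
    reads: list[NucSeq] = []
    placements: list[ReadPlacement] = []
    width = len(str(cfg.read_count))
    for k in range(cfg.read_count):
        L = int(lengths[k])
        start = int(mids[k]) - L // 2
        start = min(max(start, 0), cfg.genome_length - L)
        end = start + L
        strand = SENSE if strands[k] else ANTISENSE
        read_id = f"read{k:0{width}d}"
        sub = genome.seq[start:end]
        if strand == ANTISENSE:
            sub = reverse_complement(NucSeq(id=read_id, seq=sub)).seq
        sub = _apply_noise(sub, cfg.noise, rng)
        reads.append(NucSeq(id=read_id, seq=sub, strand=SENSE))
        placements.append(
            ReadPlacement(read_id=read_id, chrom=cfg.chrom, start=start, end=end, strand=strand)
        )
    truth.placements = placements
    truth.read_families = _true_families(placements, truth.annotation)
    return reads, placements


def _true_families(
    placements: list[ReadPlacement], annotation: RepeatAnnotation
) -> dict[str, str]:
    ivals = sorted(annotation, key=lambda r: r.start)
    starts = np.array([r.start for r in ivals])
    ends = np.array([r.end for r in ivals])
    out: dict[str, str] = {}
    for p in placements:
        i = int(np.searchsorted(starts, p.midpoint, side="right")) - 1
        if i >= 0 and p.midpoint < ends[i]:
            out[p.read_id] = ivals[i].family
        else:
            out[p.read_id] = "."
    return out


# ---------------------------------------------------------------------------
# composition fixtures
# ---------------------------------------------------------------------------

def make_rap_set(
    n: int,
    length: int,
    ctd_fraction: float,
    bg: BackgroundModel | None = None,
    seed: int = 0,
) -> list[NucSeq]:
    """Mosaic sequences mixing CTD reverse-translation with background.

    Each codon position is, with probability ``ctd_fraction``, a codon
    reverse-translated from the YSPTSPS heptad (tracking heptad phase),
    otherwise three i.i.d. background bases; a trailing partial codon
    is background. ctd_fraction 0 is pure background; ctd_fraction 1
    with frame-0 translation is exact heptads.
    """
    if not (0.0 <= ctd_fraction <= 1.0):
        raise ValueError("ctd_fraction must lie in [0, 1]")
    if length < 5:
        raise ValueError("length must be >= 5")
    bg = bg or BackgroundModel.human_genome()
    rng = np.random.default_rng(seed)
    out: list[NucSeq] = []
    n_codons, tail = divmod(length, 3)
    for k in range(n):
        parts = []
        for i in range(n_codons):
            if rng.random() < ctd_fraction:
                aa = CTD_HEPTAD[i % len(CTD_HEPTAD)]
                codons = _CODONS_BY_AA[aa]
                parts.append(codons[rng.integers(len(codons))])
            else:
                parts.append(_random_bases(3, bg, rng).tobytes().decode())
        if tail:
            parts.append(_random_bases(tail, bg, rng).tobytes().decode())
        out.append(NucSeq(id=f"rap{k:04d}", seq="".join(parts)))
    return out


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """The same scenario under a different seed."""
    return replace(cfg, seed=seed)
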