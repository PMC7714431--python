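"""End-to-end orchestration: simulate -> enrich -> ctd-align -> codon-bias.

Each stage reads the previous stage's declared files from the output
directory, so a failure in stage k leaves the outputs of earlier stages
intact, and stage subsets can be re-run. Every run writes a manifest
(command, config snapshot, seeds, package version, sha256 digests of
the outputs, timestamp); numeric TSV output is rendered at 6
significant digits so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .alignment import (
    AlignmentResult,
    ScoringScheme,
    best_ctd_fragment,
    ctd_protein,
)
from .ctd_bias import BackgroundModel, bias_test, codon_usage
from .enrichment import (
    assign_reads,
    ca_richness,
    contig_stacks,
    fold_enrichment,
    read_placements,
    write_placements,
)
from .seqcore import (
    NucSeq,
    ProteinSeq,
    STANDARD_CODE,
    read_bed,
    read_fasta,
    reverse_complement,
    translate_three_frames,
    write_bed,
    write_fasta,
    write_table,
)
from .synthetic_data import FamilySpec, SimConfig, build_genome, sample_reads

logger = logging.getLogger("rapscan")

STAGES = ("simulate", "enrich", "ctd_align", "codon_bias")

DEFAULT_CONFIG: dict = {
    "genome_length": 50_000,
    "background": [0.295, 0.205, 0.205, 0.295],
    "families": [
        {"name": "ACRO1_like", "unit_length": 147, "copies": 4,
         "builder": "ctd_reverse_translation", "strand_rule": "both",
         "affinity_weight": 50.0},
        {"name": "CA_simple", "unit_length": 60, "copies": 5,
         "builder": "simple_repeat", "motif": "CA", "strand_rule": "both",
         "affinity_weight": 20.0},
    ],
    "read_count": 1000,
    "read_length_range": [30, 400],
    "noise": 0.0,
    "n_sets": 1000,
    "n_heptads": 52,
    "stages": list(STAGES),
}


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Console + optional per-run file logging."""
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(sh)
    if out_dir is not None:
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(config: dict, seed: int) -> SimConfig:
    fams = tuple(
        FamilySpec(
            name=f["name"],
            unit_length=int(f["unit_length"]),
            copies=int(f["copies"]),
            builder=f.get("builder", "random"),
            motif=f.get("motif"),
            strand_rule=f.get("strand_rule", "both"),
            affinity_weight=float(f.get("affinity_weight", 1.0)),
        )
        for f in config.get("families", [])
    )
    return SimConfig(
        genome_length=int(config.get("genome_length", 100_000)),
        bg=BackgroundModel(base_freqs=tuple(config.get("background", [0.295, 0.205, 0.205, 0.295]))),
        families=fams,
        read_count=int(config.get("read_count", 10_000)),
        read_length_range=tuple(config.get("read_length_range", [30, 400])),
        noise=float(config.get("noise", 0.0)),
        seed=seed,
    )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream file {path} (run earlier stages first)"
        )
    return path


def longest_clean_segment(p: ProteinSeq) -> ProteinSeq:
    """Longest run without stops or unknowns, for alignment input."""
    best = ""
    for seg in p.seq.replace("X", "*").split("*"):
        if len(seg) > len(best):
            best = seg
    if not best:
        raise ValueError(f"{p.id!r}: no stop-free segment to align")
    return ProteinSeq(id=f"{p.id}|clean", seq=best)


def best_frame_ctd_alignment(
    nuc: NucSeq, ctd: ProteinSeq, scheme: ScoringScheme | None = None
) -> tuple[int, int, AlignmentResult]:
    """Scan all three frames x all equal-length CTD windows.

    Each frame's translation is reduced to its longest stop-free
    segment before the fragment scan. Returns (frame, fragment_start,
    result) of the best-scoring combination; frame ties go to the
    lowest frame.
    """
    best = None
    for frame, prot in enumerate(translate_three_frames(nuc)):
        try:
            clean = longest_clean_segment(prot)
        except ValueError:
            continue
        if len(clean) > len(ctd):
            clean = ProteinSeq(id=clean.id, seq=clean.seq[: len(ctd)])
        start, res = best_ctd_fragment(clean, ctd, scheme)
        if best is None or res.score > best[2].score:
            best = (frame, start, res)
    if best is None:
        raise ValueError(f"{nuc.id!r}: no frame yields an alignable segment")
    return best


def format_alignment(result: AlignmentResult, name_a: str = "query", name_b: str = "ctd") -> str:
    """Three-line text block: query, match line, subject."""
    mid = "".join(
        "|" if x == y and x != "-" else " "
        for x, y in zip(result.aligned_a, result.aligned_b)
    )
    w = max(len(name_a), len(name_b), 5)
    return (
        f"{name_a:<{w}} {result.aligned_a}\n"
        f"{'':<{w}} {mid}\n"
        f"{name_b:<{w}} {result.aligned_b}\n"
    )


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "rapscan_out",
    seed: int = 0,
    stages: list[str] | None = None,
) -> Path:
    """Run the requested stages in order, writing one report directory.

    Stage outputs: simulate -> genome.fasta, repeats.bed, reads.fasta,
    placements.tsv; enrich -> enrichment.tsv, contigs.tsv,
    ca_richness.tsv; ctd_align -> alignment.txt, alignment.tsv;
    codon_bias -> bias.tsv, codon_usage.tsv. A manifest.json is always
    written last.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    stages = list(stages if stages is not None else config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    outputs: list[Path] = []

    scheme = ScoringScheme()
    ctd = ctd_protein(int(config.get("n_heptads", 52)))

    if "simulate" in stages:
        logger.info("stage simulate: genome %d bp, %d reads",
                    config["genome_length"], config["read_count"])
        cfg = _sim_config(config, seed)
        genome, annot, truth = build_genome(cfg)
        reads, placements = sample_reads(genome, truth, cfg)
        write_fasta([genome], out / "genome.fasta")
        write_bed(annot, out / "repeats.bed")
        write_fasta(reads, out / "reads.fasta")
        write_placements(placements, out / "placements.tsv", truth.read_families)
        outputs += [out / "genome.fasta", out / "repeats.bed",
                    out / "reads.fasta", out / "placements.tsv"]

    if "enrich" in stages:
        annot = read_bed(_require(out / "repeats.bed", "enrich"))
        placements = read_placements(_require(out / "placements.tsv", "enrich"))
        genome = read_fasta(_require(out / "genome.fasta", "enrich"), kind="nuc")[0]
        chrom_lengths = {genome.id: len(genome)}
        logger.info("stage enrich: %d placements, %d families",
                    len(placements), len(annot.families()))
        result = assign_reads(placements, annot, chrom_lengths)
        rows = []
        for fc in result.family_counts:
            rec = fold_enrichment(fc, total_reads=len(placements))
            rows.append({
                "family": fc.family, "sense": fc.sense_count,
                "antisense": fc.antisense_count,
                "dominant_strand": rec.dominant_strand,
                "fold_enrichment": rec.fold_enrichment,
            })
        rows.append({"family": "unannotated", "sense": result.unannotated,
                     "antisense": 0, "dominant_strand": ".", "fold_enrichment": 0.0})
        write_table(rows, out / "enrichment.tsv")
        stacks = contig_stacks(placements, chrom_lengths)
        write_table(
            [{"chrom": s.chrom, "window_start": s.window_start,
              "window_end": s.window_end, "read_count": s.read_count}
             for s in stacks] or [{"chrom": ".", "window_start": 0,
                                   "window_end": 0, "read_count": 0}],
            out / "contigs.tsv",
        )
        reads = read_fasta(_require(out / "reads.fasta", "enrich"), kind="nuc")
        bg = BackgroundModel(base_freqs=tuple(config["background"]))
        ca = ca_richness(reads, bg, n_perm=max(int(config.get("n_sets", 1000)), 100), seed=seed + 2)
        write_table([{
            "observed_ca_fraction": ca.observed_fraction, "z": ca.z,
            "p_empirical": ca.p_empirical,
            "ca_dinucleotide_freq": ca.ca_dinucleotide_freq,
        }], out / "ca_richness.tsv")
        outputs += [out / "enrichment.tsv", out / "contigs.tsv", out / "ca_richness.tsv"]

    if "ctd_align" in stages:
        genome = read_fasta(_require(out / "genome.fasta", "ctd_align"), kind="nuc")[0]
        annot = read_bed(_require(out / "repeats.bed", "ctd_align"))
        ctd_fams = {f["name"] for f in config.get("families", [])
                    if f.get("builder") == "ctd_reverse_translation"}
        target = next((r for r in annot if r.family in ctd_fams), None)
        if target is None:
            raise ValueError("stage 'ctd_align': no ctd_reverse_translation family planted")
        unit = NucSeq(id=target.family, seq=genome.seq[target.start:target.end])
        if target.strand == "-":
            unit = reverse_complement(unit)
        frame, start, res = best_frame_ctd_alignment(unit, ctd, scheme)
        logger.info("stage ctd_align: frame %d, CTD window %d, %d/%d identical",
                    frame, start, res.identities, res.aligned_length)
        (out / "alignment.txt").write_text(format_alignment(res, unit.id, "PolII_CTD"))
        write_table([{
            "query_id": unit.id, "frame": frame, "fragment_start": start,
            "score": res.score, "identities": res.identities,
            "aligned_length": res.aligned_length,
        }], out / "alignment.tsv")
        outputs += [out / "alignment.txt", out / "alignment.tsv"]

    if "codon_bias" in stages:
        reads = read_fasta(_require(out / "reads.fasta", "codon_bias"), kind="nuc")
        reads = [r for r in reads if len(r) >= 5]
        bg = BackgroundModel(base_freqs=tuple(config["background"]))
        n_sets = int(config.get("n_sets", 1000))
        logger.info("stage codon_bias: %d sequences, %d null sets", len(reads), n_sets)
        res = bias_test(reads, bg=bg, n_sets=n_sets, seed=seed + 3)
        write_table([{
            "observed_jsd": res.observed_jsd, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "z": res.z,
            "p_empirical": res.p_empirical, "p_gaussian": res.p_gaussian,
            "n_sets": res.n_sets,
        }], out / "bias.tsv")
        usage = codon_usage(reads)
        write_table(
            [{"codon": c, "count": n, "aa": STANDARD_CODE.table[c]}
             for c, n in sorted(usage.counts.items())],
            out / "codon_usage.tsv",
        )
        outputs += [out / "bias.tsv", out / "codon_usage.tsv"]

    manifest = {
        "command": "run_pipeline",
        "stages": stages,
        "config": config,
        "seed": seed,
        "version": __version__,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
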