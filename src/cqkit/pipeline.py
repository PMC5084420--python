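"""End-to-end orchestration: simulate -> count -> classify -> landscape -> stats.

All randomness flows from one top-level seed through named
``numpy.random.SeedSequence`` children, so each stage is reproducible on
its own and the whole run is byte-identical on re-execution with the same
config. Every run writes a manifest recording the configuration, the seed,
the package version and a SHA-256 digest of each artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cqkit import __version__, seqio
from cqkit.config import RunConfig
from cqkit.cq import (
    LABEL_X,
    LABEL_Y,
    classify_all,
    compute_cq,
    summarize_chromosomes,
    write_cq_outputs,
)
from cqkit.landscape import (
    RepeatAlignment,
    align_copy_to_consensus,
    build_landscape,
    parse_align_tsv,
    parse_crossmatch_align,
    repeat_fraction,
)
from cqkit.match import SequenceIndex, count_exact_matches
from cqkit.metrics import compute_stats
from cqkit.simulate import (
    GenomeSpec,
    ReadSimSpec,
    SexReadSet,
    TEPlantSpec,
    TruthTable,
    plant_te_copies,
    random_te_library,
    simulate_genome,
    simulate_reads,
)

logger = logging.getLogger(__name__)

# fixed offsets give each stage an independent, named random stream
STAGE_STREAMS = {"genome": 0, "te": 1, "female_reads": 2, "male_reads": 3}


def derive_seed(base_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    child = np.random.SeedSequence(
        base_seed, spawn_key=(STAGE_STREAMS[stage], extra)
    )
    return int(child.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunReport:
    outdir: Path
    summary: dict = field(default_factory=dict)

    def write(self) -> Path:
        path = self.outdir / "run_report.json"
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _confusion_matrix(records, truth: TruthTable) -> dict[str, dict[str, int]]:
    matrix: dict[str, dict[str, int]] = {}
    for r in records:
        true_class = truth.classes.get(r.contig_id, "?")
        row = matrix.setdefault(true_class, {})
        row[r.label] = row.get(r.label, 0) + 1
    return matrix


def _simulate_stage(config: RunConfig, outdir: Path):
    sim = config.data["simulate"]
    genome_spec = GenomeSpec(
        n_autosomal_contigs=int(sim["genome"]["n_autosomal_contigs"]),
        n_x_contigs=int(sim["genome"]["n_x_contigs"]),
        n_y_contigs=int(sim["genome"]["n_y_contigs"]),
        contig_length_range=tuple(int(x) for x in sim["genome"]["contig_length_range"]),
        gc_content=float(sim["genome"]["gc_content"]),
        seed=derive_seed(config.seed, "genome"),
    )
    contigs, truth = simulate_genome(genome_spec)

    te_classes: dict[str, str] = {}
    library: dict[str, str] = {}
    for i, fam in enumerate(sim["te_families"]):
        fam_seed = derive_seed(config.seed, "te", i)
        library.update(
            random_te_library([(fam["consensus_id"], int(fam["length"]))], seed=fam_seed)
        )
        te_classes[fam["consensus_id"]] = fam.get("te_class", "other")
        contigs, truth = plant_te_copies(
            contigs,
            library,
            TEPlantSpec(
                consensus_id=fam["consensus_id"],
                n_copies=int(fam["n_copies"]),
                target_divergence=float(fam["target_divergence"]),
                ts_tv_ratio=float(fam.get("ts_tv_ratio", 2.0)),
                seed=fam_seed,
            ),
            truth,
        )

    reads = {}
    for sex in ("female", "male"):
        spec = ReadSimSpec(
            sex=sex,
            depth=float(sim["reads"]["depth"]),
            read_length=int(sim["reads"]["read_length"]),
            substitution_error_rate=float(sim["reads"]["substitution_error_rate"]),
            seed=derive_seed(config.seed, f"{sex}_reads"),
        )
        reads[sex] = simulate_reads(contigs, truth, spec)

    seqio.write_fasta(outdir / "assembly.fasta", contigs.items())
    truth.write_tsv(outdir / "truth.tsv")
    truth.write_insertions_tsv(outdir / "insertions.tsv")
    if library:
        seqio.write_fasta(outdir / "te_library.fasta", library.items())
    for sex in ("female", "male"):
        reads[sex].write_fastq(outdir / f"{sex}.fastq")
    return contigs, truth, reads, library, te_classes


def _planted_alignments(
    contigs: dict[str, str],
    truth: TruthTable,
    library: dict[str, str],
    te_classes: dict[str, str],
) -> list[RepeatAlignment]:
    """Score every planted insertion against its consensus via the
    production alignment path."""
    alignments = []
    for ins in truth.insertions:
        copy_seq = contigs[ins.contig_id][ins.start - 1 : ins.end]
        copy_aln, cons_aln = align_copy_to_consensus(copy_seq, library[ins.consensus_id])
        alignments.append(
            RepeatAlignment.from_gapped(
                ins.contig_id,
                ins.start,
                ins.end,
                ins.consensus_id,
                te_classes.get(ins.consensus_id, "other"),
                copy_aln,
                cons_aln,
            )
        )
    return alignments


def load_repeat_alignments(path: str | Path) -> list[RepeatAlignment]:
    """Dispatch on extension: ``.align`` blocks, anything else TSV dialect."""
    path = Path(path)
    if path.suffix == ".align":
        return parse_crossmatch_align(path)
    return parse_align_tsv(path)


def run_pipeline(config: RunConfig, make_plots: bool = False) -> RunReport:
    """Execute every configured stage and write artifacts plus a manifest."""
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"mode": config.mode, "seed": config.seed}

    if config.mode == "simulate":
        logger.info("stage simulate: generating genome and read pools")
        contigs, truth, reads, library, te_classes = _simulate_stage(config, outdir)
        female_reads, male_reads = reads["female"], reads["male"]
        repeat_alignments = (
            _planted_alignments(contigs, truth, library, te_classes)
            if truth.insertions
            else []
        )
    else:
        logger.info("stage load: reading user inputs")
        inputs = config.data["inputs"]
        contigs = seqio.read_fasta_dict(inputs["assembly"])
        truth = None
        female_reads = SexReadSet.from_fastx(inputs["female_reads"], "female")
        male_reads = SexReadSet.from_fastx(inputs["male_reads"], "male")
        repeat_alignments = (
            load_repeat_alignments(inputs["repeat_alignments"])
            if inputs.get("repeat_alignments")
            else []
        )

    logger.info("stage count: exact whole-read matching (%d contigs)", len(contigs))
    index = SequenceIndex(contigs)
    female_counts = count_exact_matches(index, female_reads)
    male_counts = count_exact_matches(index, male_reads)
    female_counts.write_tsv(outdir / "female_counts.tsv")
    male_counts.write_tsv(outdir / "male_counts.tsv")
    summary["mapped_fraction"] = {
        "female": female_counts.mapped_reads / max(female_counts.total_reads, 1),
        "male": male_counts.mapped_reads / max(male_counts.total_reads, 1),
    }

    logger.info("stage cq: chromosome-quotient classification")
    thresholds = config.thresholds()
    lengths = {c: len(s) for c, s in contigs.items()}
    records = classify_all(
        compute_cq(female_counts, male_counts, thresholds, lengths), thresholds
    )
    chrom_summary = write_cq_outputs(records, thresholds, outdir / "cq", contigs)
    summary["chromosomes"] = chrom_summary.to_dict()
    if truth is not None:
        summary["confusion_matrix"] = _confusion_matrix(records, truth)

    if repeat_alignments:
        logger.info("stage landscape: %d repeat alignments", len(repeat_alignments))
        land_cfg = config.data["landscape"]
        table = build_landscape(
            repeat_alignments,
            bin_width=float(land_cfg["bin_width"]),
            cap=float(land_cfg["cap"]),
        )
        table.write_tsv(outdir / "landscape.tsv")
        spans = [(a.contig_id, a.start, a.end) for a in repeat_alignments]
        repeat_bp, frac = repeat_fraction(spans, lengths)
        summary["repeats"] = {
            "aligned_bp": table.total_bp,
            "saturated_bp": table.saturated_bp,
            "genome_repeat_bp": repeat_bp,
            "genome_repeat_fraction": frac,
        }
        for label in (LABEL_X, LABEL_Y):
            member_lengths = {r.contig_id: r.length for r in records if r.label == label}
            if member_lengths:
                sub = [s for s in spans if s[0] in member_lengths]
                bp, sub_frac = repeat_fraction(sub, member_lengths) if sub else (0, 0.0)
                summary["repeats"][f"putative_{label}_repeat_fraction"] = sub_frac

    logger.info("stage stats: assembly metrics")
    stats = compute_stats(contigs, length_floor=int(config.data["stats"]["min_length"]))
    stats.write_json(outdir / "assembly_stats.json")
    stats.write_tsv(outdir / "assembly_stats.tsv")
    summary["assembly_stats"] = stats.to_dict()

    if make_plots:
        from cqkit import plots

        plots.cq_histogram(records, outdir / "cq_histogram.png")
        if repeat_alignments:
            plots.landscape_profile(table, outdir / "landscape.png")

    report = RunReport(outdir=outdir, summary=summary)
    report_path = report.write()
    _write_manifest(config, outdir, report_path)
    return report


def _write_manifest(config: RunConfig, outdir: Path, report_path: Path) -> None:
    artifacts = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "cqkit_version": __version__,
        "seed": config.seed,
        "config": config.data,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
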