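"""Orchestration: demo configurations, stage runners and the run manifest.

Stages exchange plain FASTA/FASTQ/SAM/BED/TSV files so that any stage can be
run standalone on externally supplied data; the manifest records the config,
derived seeds and a digest of every output, making reruns checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering, coverage, expression, io_formats, landscape, qpcr
from . import simulate as sim

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


def demo_config(seed: int = 0) -> sim.SimulationConfig:
    """The packaged demo: a ~540 kb A complement with six TE families.

    Three insertion waves (divergence means 5, 15 and 25%), two B-amplified
    families (400 Gypsy and 200 hAT chrB copies), four samples (a 0B
    reference, a second 0B, a 1B and a 2B individual) at 20x depth.
    """
    burst = sim.BurstSpec
    families = (
        sim.TEFamilySpec("Tc1-1", "TcMar-Tc1", "DNA", 1000,
                         (burst(0.15, 0.01, 60),)),
        sim.TEFamilySpec("hAT-1", "hAT-Ac", "DNA", 600,
                         (burst(0.05, 0.01, 80),), b_copies=200),
        sim.TEFamilySpec("L2-1", "L2", "LINE", 1500,
                         (burst(0.15, 0.01, 20), burst(0.25, 0.01, 20))),
        sim.TEFamilySpec("Gypsy-1", "Gypsy", "LTR", 1000,
                         (burst(0.25, 0.01, 40),), b_copies=400),
        sim.TEFamilySpec("Pao-1", "Pao", "LTR", 800,
                         (burst(0.25, 0.01, 25),)),
        sim.TEFamilySpec("Sat-1", "Satellite", "Satellite", 300,
                         (burst(0.05, 0.01, 40),)),
    )
    samples = (
        sim.SampleMeta("M1-0B", "M", 0, is_reference=True),
        sim.SampleMeta("F1-0B", "F", 0),
        sim.SampleMeta("M2-1B", "M", 1),
        sim.SampleMeta("M4-2B", "M", 2),
    )
    return sim.SimulationConfig(
        seed=seed,
        background_length=300_000,
        families=families,
        samples=samples,
        mean_depth=20.0,
        read_length=100,
        # a long single-copy anchor keeps the normalization scale tight:
        # the anchor's mean-depth estimate has relative sd ~ sqrt(D*r/L)/D,
        # ~3.5% at 4 kb and 20x with 100 bp reads
        hprt_length=4000,
    )


def clustering_demo_config(seed: int = 0) -> sim.SimulationConfig:
    """A small-B scenario for comparative clustering.

    The B haplotype is a minor fraction of the genome (as in real taxa), so
    a cluster's 2B:0B read-proportion enrichment tracks (c_A + c_B)/c_A for
    the amplified family: here 40 A copies and 80 chrB copies.
    """
    burst = sim.BurstSpec
    families = (
        sim.TEFamilySpec("Gypsy-1", "Gypsy", "LTR", 500,
                         (burst(0.03, 0.005, 40),), b_copies=80,
                         b_divergence=0.01),
        sim.TEFamilySpec("Tc1-1", "TcMar-Tc1", "DNA", 500,
                         (burst(0.03, 0.005, 48),)),
        sim.TEFamilySpec("L2-1", "L2", "LINE", 600,
                         (burst(0.03, 0.005, 40),)),
    )
    samples = (
        sim.SampleMeta("M1-0B", "M", 0, is_reference=True),
        sim.SampleMeta("M4-2B", "M", 2),
    )
    return sim.SimulationConfig(
        seed=seed,
        background_length=480_000,
        families=families,
        samples=samples,
        mean_depth=2.0,
        read_length=100,
        chrb_background_fraction=0.02,
    )


def demo_expansion_analysis(
    seed: int = 0, config: sim.SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Simulate the demo study and run the coverage-ratio analysis in memory.

    Returns (per-locus ratios, per-element expansion summary, total reads
    simulated across samples).
    """
    config = config or demo_config(seed)
    rng = np.random.default_rng(stage_seed(seed, "simulate"))
    truth, library = sim.build_reference_genome(config, rng)
    if any(f.b_copies > 0 for f in config.families):
        truth = sim.build_b_haplotype(truth, config, rng, library)
    alignments = {}
    n_reads = 0
    for sample in config.samples:
        reads, aln = sim.simulate_wgs_sample(truth, sample, config, rng)
        n_reads += len(reads)
        alignments[sample.sample_id] = aln
    annotation = [iv for iv in truth.annotation if iv.contig != "chrB"]
    ratios, summary = coverage.coverage_analysis(
        alignments, annotation, config.reference_sample.sample_id
    )
    return ratios, summary, n_reads


def demo_clustering_analysis(
    seed: int = 0, n_per_origin: int = 3000
) -> tuple[list, int, dict]:
    """Simulate the small-B scenario and cluster 0B vs 2B read samples.

    Returns (clusters, singleton count, info dict with the amplified family's
    nominal enrichment (c_A + c_B)/c_A and element names).
    """
    config = clustering_demo_config(seed)
    rng = np.random.default_rng(stage_seed(seed, "simulate"))
    truth, library = sim.build_reference_genome(config, rng)
    truth = sim.build_b_haplotype(truth, config, rng, library)
    reads = {
        s.sample_id: sim.simulate_wgs_sample(truth, s, config, rng)[0]
        for s in config.samples
    }
    origin_b = next(s.sample_id for s in config.samples if s.b_count > 0)
    origin_0 = config.reference_sample.sample_id
    clusters, singletons, sampled = clustering.comparative_clustering(
        reads, n_per_origin, origin_b, origin_0,
        np.random.default_rng(stage_seed(seed, "cluster")),
    )
    reads_by_id = {r.read_id: r for r in sampled}
    for cluster in clusters:
        if cluster.size >= 10:
            clustering.annotate_cluster(cluster, reads_by_id, library, max_reads=10)
    amplified = next(f for f in config.families if f.b_copies > 0)
    info = {
        "amplified_element": amplified.element,
        "nominal_enrichment": (amplified.a_copies + amplified.b_copies)
        / amplified.a_copies,
        "null_elements": [
            f.element for f in config.families if f.b_copies == 0
        ],
        "origin_b": origin_b,
        "origin_0": origin_0,
    }
    return clusters, singletons, info


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: sim.SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["families"] = [
        {**dataclasses.asdict(f), "bursts": [list(b) for b in f.bursts]}
        for f in config.families
    ]
    d["samples"] = [dataclasses.asdict(s) for s in config.samples]
    return d


def config_from_dict(d: Mapping) -> sim.SimulationConfig:
    d = dict(d)
    d["families"] = tuple(
        sim.TEFamilySpec(
            **{
                **f,
                "bursts": tuple(sim.BurstSpec(*b) for b in f.get("bursts", [])),
            }
        )
        for f in d.get("families", [])
    )
    d["samples"] = tuple(sim.SampleMeta(**s) for s in d.get("samples", []))
    return sim.SimulationConfig(**d)


def load_config(path: str | Path) -> sim.SimulationConfig:
    with open(path) as handle:
        return config_from_dict(json.load(handle))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

class RunManifest:
    def __init__(self, config: sim.SimulationConfig, master_seed: int):
        self.data = {
            "format_version": FORMAT_VERSION,
            "master_seed": master_seed,
            "config": config_to_dict(config),
            "stages": [],
        }

    def record(self, stage: str, seed: int | None, outputs: Sequence[Path],
               wall_time: float) -> None:
        self.data["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "wall_time_s": round(wall_time, 3),
                "outputs": {
                    str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
                    for p in outputs
                },
            }
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(self.data, out, indent=1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(
    config: sim.SimulationConfig, outdir: Path, master_seed: int
) -> dict[str, Path]:
    """Generate genome, truth annotation, read sets, counts and Ct tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(stage_seed(master_seed, "simulate"))
    truth, library = sim.build_reference_genome(config, rng)
    if any(f.b_copies > 0 for f in config.families):
        truth = sim.build_b_haplotype(truth, config, rng, library)
    outputs: dict[str, Path] = {}

    def path(name: str) -> Path:
        outputs[name] = outdir / name
        return outputs[name]

    io_formats.write_fasta(library, path("library.fasta"))
    io_formats.write_fasta(
        [(c, truth.sequences[c]) for c in truth.a_contigs], path("genome.fasta")
    )
    io_formats.write_bed(
        [iv for iv in truth.annotation if iv.contig != "chrB"],
        path("annotation.bed"),
    )
    io_formats.write_bed(truth.intervals_on("chrB"), path("annotation_chrB.bed"))
    sheet = pd.DataFrame(
        [
            (s.sample_id, s.sex, s.b_count, int(s.is_reference))
            for s in config.samples
        ],
        columns=["sample_id", "sex", "b_count", "is_reference"],
    )
    io_formats.write_tsv_table(sheet, path("samples.tsv"))
    header = {c: len(truth.sequences[c]) for c in truth.a_contigs}
    for sample in config.samples:
        reads, alignments = sim.simulate_wgs_sample(truth, sample, config, rng)
        io_formats.write_fastq(reads, path(f"{sample.sample_id}.fastq"))
        io_formats.write_sam(alignments, header, path(f"{sample.sample_id}.sam"))

    elements = [(f.element, f.class_label) for f in config.families]
    de_spec = {}
    if config.families:
        de_spec = {config.families[0].element: 4.0}
        if len(config.families) > 1:
            de_spec[config.families[-1].element] = 0.25
    counts, truth_labels = sim.simulate_expression_counts(
        elements, 6, [200.0] * len(elements), 0.1, de_spec, rng
    )
    counts.reset_index().pipe(io_formats.write_tsv_table, path("rna_counts.tsv"))
    io_formats.write_tsv_table(truth_labels.attrs["groups"], path("rna_samples.tsv"))
    io_formats.write_tsv_table(truth_labels, path("rna_truth.tsv"))

    amplified = [f for f in config.families if f.b_copies > 0]
    target = amplified[0] if amplified else None
    copy_numbers = {}
    for s in config.samples:
        copies = 2.0 * (target.a_copies if target else 1)
        if target:
            copies += target.b_copies * s.b_count
        group = "B+" if s.b_count > 0 else "B-"
        copy_numbers[s.sample_id] = (copies, group)
    ct = sim.simulate_ct_values(copy_numbers, c0=24.0, noise_sd=0.1, rng=rng)
    io_formats.write_tsv_table(ct, path("ct.tsv"))
    return outputs


def stage_coverage(
    annotation_bed: Path,
    sample_sheet: Path,
    sam_dir: Path,
    outdir: Path,
    tau: float = 2.0,
    min_ref_fraction: float = 0.25,
    min_mapq: int = 0,
    sum_mode: str = "excess",
) -> dict[str, Path]:
    """Per-locus HPRT-normalized ratios and the expansion summary table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = io_formats.read_bed(annotation_bed)
    sheet = io_formats.read_tsv_table(sample_sheet)
    reference = sheet.loc[sheet["is_reference"] == 1, "sample_id"].iloc[0]
    alignments = {
        row.sample_id: io_formats.read_sam(Path(sam_dir) / f"{row.sample_id}.sam")
        for row in sheet.itertuples()
    }
    ratios, summary = coverage.coverage_analysis(
        alignments, annotation, reference, tau, min_ref_fraction, min_mapq, sum_mode
    )
    ratios_path = outdir / "coverage_ratios.tsv"
    ratios.reset_index().pipe(io_formats.write_tsv_table, ratios_path)
    summary_path = outdir / "expansion_summary.tsv"
    summary.reset_index().pipe(io_formats.write_tsv_table, summary_path)
    return {"coverage_ratios.tsv": ratios_path,
            "expansion_summary.tsv": summary_path}


def stage_landscape(
    genome_fasta: Path,
    annotation_bed: Path,
    library_fasta: Path,
    outdir: Path,
    bin_width: float = 1.0,
    cpg_adjust: bool = False,
    min_prominence: float = 0.10,
) -> dict[str, Path]:
    """Per-copy divergences, the landscape matrix and burst peaks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = dict(io_formats.read_fasta(genome_fasta))
    annotation = io_formats.read_bed(annotation_bed)
    library = dict(io_formats.read_fasta(library_fasta))
    divergences = landscape.genome_copy_divergences(
        sequences, annotation, library, cpg_adjust
    )
    genome_size = sum(len(s) for s in sequences.values())
    matrix = landscape.build_landscape(divergences, bin_width, genome_size)
    peaks = landscape.detect_bursts(matrix, min_prominence)
    long = landscape.landscape_long(matrix, genome_size)
    landscape_path = outdir / "landscape.tsv"
    io_formats.write_tsv_table(long, landscape_path)
    peaks_path = outdir / "bursts.tsv"
    io_formats.write_tsv_table(
        pd.DataFrame({"divergence_pct": peaks}), peaks_path
    )
    div_path = outdir / "copy_divergences.tsv"
    io_formats.write_tsv_table(pd.DataFrame(divergences), div_path)
    return {"landscape.tsv": landscape_path, "bursts.tsv": peaks_path,
            "copy_divergences.tsv": div_path}


def stage_cluster(
    fastq_by_origin: Mapping[str, Path],
    origin_b: str,
    origin_0: str,
    outdir: Path,
    n_per_origin: int = 500,
    seed: int = 0,
    library_fasta: Path | None = None,
    min_size: int = 50,
    min_enrichment: float = 3.0,
    **edge_kwargs,
) -> dict[str, Path]:
    """Comparative clustering of two read sets and B-cluster selection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = {
        origin: io_formats.read_fastq(path, origin)
        for origin, path in fastq_by_origin.items()
    }
    rng = np.random.default_rng(seed)
    clusters, singletons, sampled = clustering.comparative_clustering(
        reads, n_per_origin, origin_b, origin_0, rng, **edge_kwargs
    )
    reads_by_id = {r.read_id: r for r in sampled}
    if library_fasta is not None:
        library = io_formats.read_fasta(library_fasta)
        for cluster in clusters:
            clustering.annotate_cluster(
                cluster, reads_by_id, library, max_reads=20
            )
    report = clustering.select_b_clusters(
        clusters, origin_b, origin_0, min_size, min_enrichment
    )
    all_path = outdir / "clusters.tsv"
    io_formats.write_tsv_table(
        pd.DataFrame(
            {
                "cluster": [c.cluster_id for c in clusters],
                "size": [c.size for c in clusters],
                f"{origin_0}_reads": [
                    c.origin_counts.get(origin_0, 0) for c in clusters
                ],
                f"{origin_b}_reads": [
                    c.origin_counts.get(origin_b, 0) for c in clusters
                ],
                "enrichment": [c.enrichment for c in clusters],
                "annotation": [c.annotation for c in clusters],
            }
        ),
        all_path,
    )
    report_path = outdir / "b_clusters.tsv"
    io_formats.write_tsv_table(report, report_path)
    assign_path = outdir / "read_assignments.tsv"
    rows = [
        (m, c.cluster_id) for c in clusters for m in c.members
    ]
    io_formats.write_tsv_table(
        pd.DataFrame(rows, columns=["read_id", "cluster"]), assign_path
    )
    return {"clusters.tsv": all_path, "b_clusters.tsv": report_path,
            "read_assignments.tsv": assign_path}


def stage_express(
    counts_tsv: Path,
    samples_tsv: Path,
    outdir: Path,
    truth_tsv: Path | None = None,
    lfc_cut: float = expression.DEFAULT_LFC_CUT,
    fdr_cut: float = expression.DEFAULT_FDR_CUT,
) -> dict[str, Path]:
    """Differential expression per tissue plus the call summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = io_formats.read_tsv_table(counts_tsv).set_index("element")
    sheet = io_formats.read_tsv_table(samples_tsv)
    classes = None
    if truth_tsv is not None:
        truth = io_formats.read_tsv_table(truth_tsv)
        classes = dict(zip(truth["element"], truth["class_label"]))
    outputs: dict[str, Path] = {}
    summaries = []
    for tissue, block in sheet.groupby("tissue"):
        groups = pd.Series(block["group"].values, index=block["sample_id"])
        table = expression.differential_expression(
            counts[block["sample_id"]], groups, classes,
            lfc_cut=lfc_cut, fdr_cut=fdr_cut,
        )
        de_path = outdir / f"de_{tissue}.tsv"
        table.reset_index().pipe(io_formats.write_tsv_table, de_path)
        outputs[de_path.name] = de_path
        summaries.append({"tissue": tissue, **expression.summarize_calls(table)})
    summary_path = outdir / "de_summary.tsv"
    io_formats.write_tsv_table(pd.DataFrame(summaries), summary_path)
    outputs["de_summary.tsv"] = summary_path
    return outputs


def stage_gdr(ct_tsv: Path, outdir: Path) -> dict[str, Path]:
    """Gene dosage ratios and the B+ vs B- group summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ct = io_formats.read_tsv_table(ct_tsv)
    gdr = qpcr.gdr_table(ct)
    gdr_path = outdir / "gdr.tsv"
    io_formats.write_tsv_table(gdr, gdr_path)
    summary = qpcr.group_fold(gdr)
    summary_path = outdir / "gdr_summary.tsv"
    io_formats.write_tsv_table(pd.DataFrame([summary]), summary_path)
    return {"gdr.tsv": gdr_path, "gdr_summary.tsv": summary_path}


def run_all(
    config: sim.SimulationConfig,
    outdir: str | Path,
    master_seed: int | None = None,
    n_per_origin: int = 300,
) -> RunManifest:
    """simulate -> coverage -> landscape -> cluster -> express -> gdr."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = config.seed if master_seed is None else master_seed
    manifest = RunManifest(config, master_seed)

    def timed(stage: str, seed: int | None, fn):
        t0 = time.monotonic()
        outputs = fn()
        manifest.record(stage, seed, list(outputs.values()),
                        time.monotonic() - t0)
        logger.info("stage %s done (%.1fs)", stage, time.monotonic() - t0)
        return outputs

    seed_sim = stage_seed(master_seed, "simulate")
    sim_out = timed("simulate", seed_sim,
                    lambda: stage_simulate(config, outdir / "simulate",
                                           master_seed))
    timed(
        "coverage", None,
        lambda: stage_coverage(
            sim_out["annotation.bed"], sim_out["samples.tsv"],
            outdir / "simulate", outdir / "coverage",
        ),
    )
    timed(
        "landscape", None,
        lambda: stage_landscape(
            sim_out["genome.fasta"], sim_out["annotation.bed"],
            sim_out["library.fasta"], outdir / "landscape",
        ),
    )
    sheet = io_formats.read_tsv_table(sim_out["samples.tsv"])
    zero_b = sheet.loc[sheet["b_count"] == 0, "sample_id"].iloc[0]
    most_b = sheet.sort_values("b_count", ascending=False)["sample_id"].iloc[0]
    seed_cluster = stage_seed(master_seed, "cluster")
    timed(
        "cluster", seed_cluster,
        lambda: stage_cluster(
            {
                zero_b: sim_out[f"{zero_b}.fastq"],
                most_b: sim_out[f"{most_b}.fastq"],
            },
            most_b, zero_b, outdir / "cluster",
            n_per_origin=n_per_origin, seed=seed_cluster,
            library_fasta=sim_out["library.fasta"],
        ),
    )
    timed(
        "express", None,
        lambda: stage_express(
            sim_out["rna_counts.tsv"], sim_out["rna_samples.tsv"],
            outdir / "express", sim_out["rna_truth.tsv"],
        ),
    )
    timed("gdr", None, lambda: stage_gdr(sim_out["ct.tsv"], outdir / "gdr"))
    manifest.save(outdir / "manifest.json")
    return manifest
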