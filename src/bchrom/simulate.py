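"""Synthetic genomes, read sets, count tables and Ct tables with known truth.

The generator emulates the study design the pipeline targets: a diploid fish
genome whose standard chromosome set (the "A complement") carries transposable
element (TE) copies inserted in divergence-structured waves, plus an optional
supernumerary B chromosome carrying hundreds of freshly amplified copies of a
few families.  Samples with 0, 1 or 2 B chromosomes are sequenced to uniform
depth; B-derived reads are assigned to their homologous A loci, which is the
mechanism that makes per-locus coverage ratios detect B amplification.

Sequence divergence is simulated by sampling each site's end state from the
exact Kimura two-parameter transition probabilities at the requested distance,
so the downstream K2P estimator is consistent for the configured divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, ReadRecord, RepeatInterval

HPRT_ELEMENT = "HPRT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# transition partner (A<->G, C<->T) indexed by ACGT
_TRANSITION = {65: 71, 67: 84, 71: 65, 84: 67}
# the two transversion partners per base
_TRANSVERSIONS = {65: (67, 84), 67: (65, 71), 71: (67, 84), 84: (65, 71)}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class BurstSpec(NamedTuple):
    """One insertion wave: copies inserted at divergence ~N(mean, sd)."""

    mean_divergence: float
    sd: float
    copies: int


@dataclass(frozen=True)
class TEFamilySpec:
    """A TE family: its consensus, its insertion waves, and B amplification."""

    element: str
    family: str
    class_label: str
    consensus_length: int
    bursts: tuple[BurstSpec, ...] = ()
    b_copies: int = 0
    b_divergence: float = 0.02
    b_divergence_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.consensus_length < 100:
            raise ConfigError(f"{self.element}: consensus_length must be >= 100")
        for burst in self.bursts:
            if burst.copies < 0 or not 0 <= burst.mean_divergence < 0.5:
                raise ConfigError(f"{self.element}: invalid burst {burst}")
            if burst.mean_divergence + 3 * burst.sd >= 0.5:
                raise ConfigError(
                    f"{self.element}: burst divergence too close to saturation"
                )
        if self.b_copies < 0:
            raise ConfigError(f"{self.element}: b_copies must be >= 0")

    @property
    def a_copies(self) -> int:
        return sum(b.copies for b in self.bursts)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sex: str
    b_count: int
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.sex not in {"M", "F"}:
            raise ConfigError(f"{self.sample_id}: sex must be M or F")
        if self.b_count not in {0, 1, 2}:
            raise ConfigError(f"{self.sample_id}: b_count must be 0, 1 or 2")
        if self.is_reference and self.b_count != 0:
            raise ConfigError("the reference sample must carry no B chromosome")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    background_length: int = 300_000
    gc_fraction: float = 0.42
    ts_tv_ratio: float = 2.0
    indel_rate: float = 0.0
    families: tuple[TEFamilySpec, ...] = ()
    hprt_length: int = 1000
    read_length: int = 100
    mean_depth: float = 20.0
    error_rate: float = 0.005
    chrb_background_fraction: float = 0.3
    samples: tuple[SampleMeta, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not 0 <= self.chrb_background_fraction < 1:
            raise ConfigError("chrb_background_fraction must be in [0, 1)")
        names = [f.element for f in self.families]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate element names in family specs")
        refs = [s for s in self.samples if s.is_reference]
        if self.samples and len(refs) != 1:
            raise ConfigError("exactly one sample must be the reference")

    @property
    def reference_sample(self) -> SampleMeta:
        return next(s for s in self.samples if s.is_reference)


@dataclass
class GenomeTruth:
    """Simulated genome plus everything the pipeline would have to infer."""

    sequences: dict[str, str]
    annotation: list[RepeatInterval]
    #: realized K2P distance per copy, keyed by (contig, start, end, element)
    divergences: dict[tuple[str, int, int, str], float]
    #: chrB copy key -> homologous A-complement copy key (same element)
    homology: dict[tuple[str, int, int, str], tuple[str, int, int, str]] = field(
        default_factory=dict
    )

    @property
    def a_contigs(self) -> list[str]:
        return [c for c in self.sequences if c != "chrB"]

    @property
    def hprt_interval(self) -> RepeatInterval:
        return next(iv for iv in self.annotation if iv.element == HPRT_ELEMENT)

    def intervals_on(self, contig: str) -> list[RepeatInterval]:
        return [iv for iv in self.annotation if iv.contig == contig]


def interval_key(iv: RepeatInterval) -> tuple[str, int, int, str]:
    return (iv.contig, iv.start, iv.end, iv.element)


# ---------------------------------------------------------------------------
# sequences and mutation
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    draws = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return draws.tobytes().decode()


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def make_family_library(
    specs: Sequence[TEFamilySpec], rng: np.random.Generator, gc_fraction: float = 0.42
) -> list[tuple[str, str]]:
    """One uniformly random consensus per element at the given GC fraction."""
    names = [s.element for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate element names in family specs")
    return [
        (s.element, random_sequence(s.consensus_length, gc_fraction, rng))
        for s in specs
    ]


def k2p_endpoint_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """Exact K2P (p, q) = (transition, transversion) site probabilities.

    ``d`` is the evolutionary distance (expected substitutions/site, multiple
    hits included) and ``kappa`` the instantaneous transition:transversion
    rate ratio, so p/q -> kappa as d -> 0.
    """
    if not 0 <= d < 0.5:
        raise ConfigError(f"divergence {d} outside [0, 0.5)")
    beta_t = d / (2.0 * (kappa + 1.0))
    alpha_t = d * kappa / (kappa + 1.0)
    p = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    q = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return p, q


def mutate_sequence(
    consensus: str,
    target_divergence: float,
    kappa: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Evolve a copy away from its consensus to a given K2P distance.

    Returns the mutated sequence and the realized substitution count.
    """
    p, q = k2p_endpoint_probabilities(target_divergence, kappa)
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    u = rng.random(arr.size)
    n_sub = 0
    ts_sites = np.nonzero(u < p)[0]
    tv_sites = np.nonzero((u >= p) & (u < p + q))[0]
    for i in ts_sites:
        arr[i] = _TRANSITION.get(arr[i], arr[i])
    pick = rng.integers(0, 2, size=tv_sites.size)
    for j, i in enumerate(tv_sites):
        partners = _TRANSVERSIONS.get(arr[i])
        if partners is not None:
            arr[i] = partners[pick[j]]
    n_sub = ts_sites.size + tv_sites.size
    seq = arr.tobytes().decode()
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r >= 1 - indel_rate / 2:
                out.append(random_sequence(int(rng.integers(1, 4)), 0.5, rng))
        seq = "".join(out)
    return seq, int(n_sub)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _insertion_points(
    n: int, background_length: int, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted insertion points separated by at least ``min_gap`` background bp.

    The gap keeps inserted copies from abutting, so no read can span two
    copies and truth intervals never touch.
    """
    effective = background_length - (n - 1) * min_gap
    if effective < 0:
        raise ConfigError(
            "background too short to space the inserted copies; "
            "enlarge the background"
        )
    raw = np.sort(rng.integers(0, effective + 1, size=n))
    return raw + np.arange(n) * min_gap


def _assemble_contig(
    contig: str,
    background: str,
    inserts: list[tuple[str, RepeatInterval, float]],
    rng: np.random.Generator,
    min_gap: int = 150,
) -> tuple[str, list[RepeatInterval], dict]:
    """Splice insert sequences into background at random spaced points.

    ``inserts`` holds (sequence, template interval with contig/start/end
    ignored, divergence).  Returns the contig sequence, final intervals and
    per-copy divergences.
    """
    points = _insertion_points(len(inserts), len(background), min_gap, rng)
    order = rng.permutation(len(inserts))
    pieces: list[str] = []
    intervals: list[RepeatInterval] = []
    divergences: dict = {}
    cursor = 0
    offset = 0
    for point, idx in zip(points, order):
        seq, template, div = inserts[idx]
        pieces.append(background[cursor:point])
        start = point + offset
        iv = replace(template, contig=contig, start=start, end=start + len(seq))
        intervals.append(iv)
        divergences[interval_key(iv)] = div
        pieces.append(seq)
        offset += len(seq)
        cursor = point
    pieces.append(background[cursor:])
    return "".join(pieces), intervals, divergences


def build_reference_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeTruth, list[tuple[str, str]]]:
    """Build the A-complement reference: background + TE copies + HPRT.

    Returns the genome truth and the consensus library used to seed copies.
    """
    library = make_family_library(config.families, rng, config.gc_fraction)
    consensus = dict(library)
    inserts: list[tuple[str, RepeatInterval, float]] = []
    template = dict(contig="chrA1", start=0, end=1)
    for spec in config.families:
        for burst in spec.bursts:
            for _ in range(burst.copies):
                d = float(
                    np.clip(rng.normal(burst.mean_divergence, burst.sd), 0.0, 0.499)
                )
                seq, _ = mutate_sequence(
                    consensus[spec.element], d, config.ts_tv_ratio,
                    config.indel_rate, rng,
                )
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    seq = reverse_complement(seq)
                iv = RepeatInterval(
                    element=spec.element, family=spec.family,
                    class_label=spec.class_label, strand=strand, **template,
                )
                inserts.append((seq, iv, d))
    hprt_iv = RepeatInterval(
        element=HPRT_ELEMENT, family=HPRT_ELEMENT, class_label="Unknown",
        strand="+", **template,
    )
    inserts.append(
        (random_sequence(config.hprt_length, config.gc_fraction, rng), hprt_iv, 0.0)
    )
    total_insert = sum(len(s) for s, _, _ in inserts)
    if total_insert >= config.background_length:
        raise ConfigError(
            f"inserted bp ({total_insert}) must be < background_length "
            f"({config.background_length}); enlarge the background"
        )
    background = random_sequence(config.background_length, config.gc_fraction, rng)
    seq, intervals, divergences = _assemble_contig(
        "chrA1", background, inserts, rng, min_gap=config.read_length + 50
    )
    return GenomeTruth({"chrA1": seq}, intervals, divergences), library


def build_b_haplotype(
    truth: GenomeTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    library: Sequence[tuple[str, str]] | None = None,
) -> GenomeTruth:
    """Append a B-chromosome haplotype carrying amplified copies.

    Each chrB copy is homologous to one uniformly chosen A-complement locus
    of the same element (the target a real aligner would pile its reads on).
    """
    amplified = [s for s in config.families if s.b_copies > 0]
    if not amplified:
        raise ConfigError("no family has b_copies > 0")
    consensus = dict(library) if library else None
    a_loci = {
        spec.element: [
            iv for iv in truth.annotation if iv.element == spec.element
        ]
        for spec in amplified
    }
    inserts: list[tuple[str, RepeatInterval, float]] = []
    template = dict(contig="chrB", start=0, end=1)
    homolog_choices: list[RepeatInterval] = []
    for spec in amplified:
        if not a_loci[spec.element]:
            raise ConfigError(
                f"{spec.element}: b_copies > 0 requires A-complement copies"
            )
        if consensus is not None:
            base = consensus[spec.element]
        else:  # fall back to the first A copy as a proxy consensus
            iv0 = a_loci[spec.element][0]
            base = truth.sequences[iv0.contig][iv0.start : iv0.end]
        for _ in range(spec.b_copies):
            d = float(
                np.clip(
                    rng.normal(spec.b_divergence, spec.b_divergence_sd), 0.0, 0.499
                )
            )
            seq, _ = mutate_sequence(
                base, d, config.ts_tv_ratio, config.indel_rate, rng
            )
            iv = RepeatInterval(
                element=spec.element, family=spec.family,
                class_label=spec.class_label, strand="+", **template,
            )
            inserts.append((seq, iv, d))
            homolog_choices.append(
                a_loci[spec.element][rng.integers(0, len(a_loci[spec.element]))]
            )
    repeat_bp = sum(len(s) for s, _, _ in inserts)
    frac = config.chrb_background_fraction
    min_gap = config.read_length + 50
    bg_len = max(
        int(repeat_bp * frac / (1.0 - frac)) + 1, len(inserts) * min_gap
    )
    background = random_sequence(bg_len, config.gc_fraction, rng)
    # keep pairing of inserts to homologs through the shuffle inside assembly:
    # assemble manually preserving order bookkeeping
    points = _insertion_points(len(inserts), len(background), min_gap, rng)
    order = rng.permutation(len(inserts))
    pieces, cursor, offset = [], 0, 0
    sequences = dict(truth.sequences)
    annotation = list(truth.annotation)
    divergences = dict(truth.divergences)
    homology = dict(truth.homology)
    for point, idx in zip(points, order):
        seq, iv_template, d = inserts[idx]
        pieces.append(background[cursor:point])
        start = point + offset
        iv = replace(iv_template, start=start, end=start + len(seq))
        annotation.append(iv)
        divergences[interval_key(iv)] = d
        homology[interval_key(iv)] = interval_key(homolog_choices[idx])
        pieces.append(seq)
        offset += len(seq)
        cursor = point
    pieces.append(background[cursor:])
    sequences["chrB"] = "".join(pieces)
    return GenomeTruth(sequences, annotation, divergences, homology)


# ---------------------------------------------------------------------------
# whole-genome sequencing
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    if n_errors == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    sites = rng.choice(arr.size, size=min(n_errors, arr.size), replace=False)
    for i in sites:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_wgs_sample(
    truth: GenomeTruth,
    sample: SampleMeta,
    config: SimulationConfig,
    rng: np.random.Generator,
    min_homology_overlap: int = 20,
) -> tuple[list[ReadRecord], list[AlignmentRecord]]:
    """Draw reads and emit their truth alignments against the A-only reference.

    A-complement contigs are sampled at ``mean_depth`` (diploid total); chrB at
    ``mean_depth * b_count / 2``.  Every chrB-origin read overlapping a B copy
    by at least ``min_homology_overlap`` bp is placed on that copy's homologous
    A locus at the same offset, with overhangs soft-clipped — emulating how an
    aligner piles B-derived reads onto their A-complement homologs.  chrB
    background reads have no homolog and are emitted unmapped.
    """
    if sample.b_count > 0 and "chrB" not in truth.sequences:
        raise ConfigError(f"{sample.sample_id}: b_count > 0 but no chrB simulated")
    L = config.read_length
    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    interval_by_key = {interval_key(iv): iv for iv in truth.annotation}

    def emit(read_seq: str, rid: str, aln: AlignmentRecord | None) -> None:
        n_err = rng.binomial(len(read_seq), config.error_rate)
        read_seq = _apply_errors(read_seq, n_err, rng)
        flag = 4 if aln is None else aln.flag
        reverse = rng.random() < 0.5
        out_seq = reverse_complement(read_seq) if reverse else read_seq
        if aln is not None and reverse:
            aln = replace(aln, flag=aln.flag | 0x10)
        reads.append(ReadRecord(rid, out_seq, origin_label=sample.sample_id))
        alignments.append(
            aln
            if aln is not None
            else AlignmentRecord(rid, "*", 0, f"{len(read_seq)}M", 0,
                                 4 | (0x10 if reverse else 0))
        )

    for contig in truth.a_contigs:
        clen = len(truth.sequences[contig])
        n = int(rng.poisson(config.mean_depth * clen / L))
        starts = rng.integers(0, clen - L + 1, size=n)
        seq = truth.sequences[contig]
        for i, s in enumerate(starts):
            rid = f"{sample.sample_id}:{contig}:{i}"
            emit(seq[s : s + L],
                 rid,
                 AlignmentRecord(rid, contig, int(s), f"{L}M", 60, 0))

    if sample.b_count > 0:
        seq = truth.sequences["chrB"]
        clen = len(seq)
        depth_b = config.mean_depth * sample.b_count / 2.0
        n = int(rng.poisson(depth_b * clen / L))
        starts = rng.integers(0, clen - L + 1, size=n)
        b_ivs = sorted(truth.intervals_on("chrB"), key=lambda iv: iv.start)
        iv_starts = np.array([iv.start for iv in b_ivs])
        for i, s in enumerate(starts):
            s = int(s)
            rid = f"{sample.sample_id}:chrB:{i}"
            read_seq = seq[s : s + L]
            j = int(np.searchsorted(iv_starts, s, side="right")) - 1
            hit = None
            for cand in (j, j + 1):
                if 0 <= cand < len(b_ivs):
                    iv = b_ivs[cand]
                    o1, o2 = max(s, iv.start), min(s + L, iv.end)
                    if o2 - o1 >= min_homology_overlap:
                        hit = (iv, o1, o2)
                        break
            if hit is None:
                emit(read_seq, rid, None)
                continue
            iv, o1, o2 = hit
            homolog = interval_by_key[truth.homology[interval_key(iv)]]
            h_start = homolog.start + (o1 - iv.start)
            matched = min(o2, iv.start + homolog.length) - o1
            if matched < min_homology_overlap or h_start >= homolog.end:
                emit(read_seq, rid, None)
                continue
            left = o1 - s
            right = L - left - matched
            cigar = (f"{left}S" if left else "") + f"{matched}M" + (
                f"{right}S" if right else ""
            )
            emit(read_seq, rid,
                 AlignmentRecord(rid, homolog.contig, h_start, cigar, 30, 0))
    return reads, alignments


# ---------------------------------------------------------------------------
# expression counts and Ct tables
# ---------------------------------------------------------------------------

def simulate_expression_counts(
    elements: Sequence[tuple[str, str]],
    n_per_group: int,
    baseline_means: Sequence[float],
    dispersion: float,
    de_spec: dict[str, float],
    rng: np.random.Generator,
    tissue: str = "tissue",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for B- vs B+ replicates.

    ``elements`` holds (element, class_label); ``de_spec`` maps element ->
    fold change applied to the B+ group mean (fold 1 for unlisted elements).
    Variance is mu + dispersion * mu^2 (dispersion 0 -> Poisson).  Returns the
    counts (elements x samples) and truth labels (element, fold, direction).
    """
    if n_per_group < 2:
        raise ConfigError("need >= 2 replicates per group")
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    samples = [f"{tissue}_B0_{i+1}" for i in range(n_per_group)] + [
        f"{tissue}_B1_{i+1}" for i in range(n_per_group)
    ]
    groups = ["B-"] * n_per_group + ["B+"] * n_per_group

    def draw(mu: float, size: int) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu, size=size)
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        return rng.negative_binomial(n_param, p_param, size=size)

    rows, labels = [], []
    for (element, class_label), mu in zip(elements, baseline_means):
        fold = de_spec.get(element, 1.0)
        counts = np.concatenate(
            [draw(mu, n_per_group), draw(mu * fold, n_per_group)]
        )
        rows.append(counts)
        direction = "ns" if fold == 1.0 else ("up" if fold > 1 else "down")
        labels.append((element, class_label, fold, direction))
    counts_df = pd.DataFrame(
        np.vstack(rows), index=[e for e, _ in elements], columns=samples
    )
    counts_df.index.name = "element"
    truth_df = pd.DataFrame(
        labels, columns=["element", "class_label", "fold", "direction"]
    )
    group_df = pd.DataFrame({"sample_id": samples, "group": groups, "tissue": tissue})
    truth_df.attrs["groups"] = group_df
    return counts_df, truth_df


def simulate_ct_values(
    copy_numbers: dict[str, tuple[float, str]],
    c0: float,
    noise_sd: float,
    rng: np.random.Generator,
    hprt_copies: float = 2.0,
) -> pd.DataFrame:
    """Ct pairs for a target element vs the single-copy normalizer.

    ``copy_numbers`` maps sample_id -> (target copies per diploid genome,
    group label).  Ct = c0 - log2(copies) + N(0, noise_sd); the normalizer is
    fixed at 2 copies per diploid genome.
    """
    rows = []
    for sample_id, (copies, group) in copy_numbers.items():
        if copies <= 0:
            raise ConfigError(f"{sample_id}: copy number must be > 0")
        ct_target = c0 - math.log2(copies) + rng.normal(0.0, noise_sd)
        ct_hprt = c0 - math.log2(hprt_copies) + rng.normal(0.0, noise_sd)
        rows.append((sample_id, group, ct_target, ct_hprt))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "ct_target", "ct_hprt"]
    )
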