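"""Comparative graph-based clustering of low-coverage read samples.

Equal-sized random read samples from two genomes (e.g. a 0B and a 2B
individual) are clustered by sequence similarity: reads sharing an exact
k-mer are candidate pairs, pairs whose best local alignment reaches the
identity/overlap thresholds become edges, and connected components are the
clusters.  A cluster's per-origin read proportions estimate the relative
genomic abundance of the underlying repeat, so clusters skewed toward the
B-carrying sample flag B-amplified elements.

This is a deliberately simplified, deterministic stand-in for hierarchical
community-detection pipelines used at genome scale: connected components on
desk-scale samples, with the conventional similarity defaults (90% identity
over at least 55% of the shorter read).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import ReadRecord
from .simulate import reverse_complement


class ClusteringError(ValueError):
    pass


@dataclass
class ReadCluster:
    cluster_id: int
    members: list[str]
    origin_counts: dict[str, int]
    enrichment: float = float("nan")
    annotation: str = ""
    annotation_tie: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def sample_reads(
    reads_by_origin: Mapping[str, Sequence[ReadRecord]],
    n_per_origin: int,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Exactly ``n_per_origin`` uniform draws without replacement per origin."""
    sampled: list[ReadRecord] = []
    for origin in sorted(reads_by_origin):
        pool = reads_by_origin[origin]
        if len(pool) < n_per_origin:
            raise ClusteringError(
                f"origin {origin} has {len(pool)} reads, need {n_per_origin}"
            )
        idx = rng.choice(len(pool), size=n_per_origin, replace=False)
        for i in idx:
            read = pool[i]
            sampled.append(
                ReadRecord(read.read_id, read.sequence, origin, read.quality)
            )
    return sampled


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    return {
        min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)
    }


def _alignment_stats(aligner, a: str, b: str) -> tuple[float, int]:
    """(identity, aligned length) of the best local alignment of a vs b."""
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0, 0
    blocks_a, blocks_b = best.aligned
    matches = 0
    columns = 0
    for (a1, a2), (b1, b2) in zip(blocks_a, blocks_b):
        columns += a2 - a1
        matches += sum(1 for i, j in zip(range(a1, a2), range(b1, b2)) if a[i] == b[j])
    if columns == 0:
        return 0.0, 0
    return matches / columns, columns


def similarity_edges(
    reads: Sequence[ReadRecord],
    k: int = 17,
    min_identity: float = 0.90,
    min_overlap_frac: float = 0.55,
) -> list[tuple[str, str]]:
    """Undirected similarity edges between reads.

    Candidate pairs share at least one exact k-mer (reverse complements
    count); an edge joins a pair whose best local alignment — forward or
    reverse-complement — has identity >= min_identity over >=
    min_overlap_frac of the shorter read.
    """
    if any(len(r.sequence) < k for r in reads):
        raise ClusteringError(f"k={k} exceeds a read length")
    index: dict[str, list[int]] = defaultdict(list)
    kmer_sets = []
    for i, read in enumerate(reads):
        kmers = _canonical_kmers(read.sequence, k)
        kmer_sets.append(kmers)
        for kmer in kmers:
            index[kmer].append(i)
    candidates: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) > 1:
            for a in range(len(hits)):
                for b in range(a + 1, len(hits)):
                    candidates.add((hits[a], hits[b]))
    aligner = _local_aligner()
    edges = []
    for i, j in sorted(candidates):
        a, b = reads[i].sequence, reads[j].sequence
        shorter = min(len(a), len(b))
        ok = False
        for b_variant in (b, reverse_complement(b)):
            identity, columns = _alignment_stats(aligner, a, b_variant)
            if identity >= min_identity and columns >= min_overlap_frac * shorter:
                ok = True
                break
        if ok:
            edges.append((reads[i].read_id, reads[j].read_id))
    return edges


def cluster_reads(
    edges: Iterable[tuple[str, str]], reads: Sequence[ReadRecord]
) -> tuple[list[ReadCluster], int]:
    """Connected components of the similarity graph.

    Components of size 1 are singletons (counted, not returned as clusters);
    clusters are numbered 1..n in decreasing size order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(r.read_id for r in reads)
    graph.add_edges_from(edges)
    origin = {r.read_id: r.origin_label for r in reads}
    components = [c for c in nx.connected_components(graph)]
    clusters = []
    singletons = 0
    for comp in components:
        if len(comp) == 1:
            singletons += 1
            continue
        members = sorted(comp)
        counts = Counter(origin[m] for m in members)
        clusters.append(ReadCluster(0, members, dict(counts)))
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    for n, cluster in enumerate(clusters, 1):
        cluster.cluster_id = n
    return clusters, singletons


def origin_composition(
    cluster: ReadCluster,
    origin_totals: Mapping[str, int],
    origin_b: str,
    origin_0: str,
    pseudocount: float = 1.0,
) -> float:
    """Enrichment E of the B-carrying origin over the B-free origin.

    E = ((n_B + psi)/N_B) / ((n_0 + psi)/N_0); the pseudocount keeps E finite
    for clusters missing one origin entirely.
    """
    n_b = cluster.origin_counts.get(origin_b, 0)
    n_0 = cluster.origin_counts.get(origin_0, 0)
    big_n_b = origin_totals[origin_b]
    big_n_0 = origin_totals[origin_0]
    if big_n_b <= 0 or big_n_0 <= 0:
        raise ClusteringError("origin totals must be > 0")
    e = ((n_b + pseudocount) / big_n_b) / ((n_0 + pseudocount) / big_n_0)
    cluster.enrichment = e
    return e


def select_b_clusters(
    clusters: Sequence[ReadCluster],
    origin_b: str,
    origin_0: str,
    min_size: int = 50,
    min_enrichment: float = 3.0,
) -> pd.DataFrame:
    """Candidate B-amplified clusters, sorted by enrichment.

    Columns mirror the comparative report: cluster id, per-origin read
    counts, enrichment, and annotation.
    """
    chosen = [
        c
        for c in clusters
        if c.size >= min_size and c.enrichment >= min_enrichment
    ]
    chosen.sort(key=lambda c: -c.enrichment)
    return pd.DataFrame(
        {
            "cluster": [c.cluster_id for c in chosen],
            f"{origin_0}_reads": [c.origin_counts.get(origin_0, 0) for c in chosen],
            f"{origin_b}_reads": [c.origin_counts.get(origin_b, 0) for c in chosen],
            "enrichment": [c.enrichment for c in chosen],
            "annotation": [c.annotation for c in chosen],
        }
    )


def annotate_cluster(
    cluster: ReadCluster,
    reads_by_id: Mapping[str, ReadRecord],
    library: Sequence[tuple[str, str]] | None = None,
    truth_elements: Mapping[str, str] | None = None,
    min_score_frac: float = 0.25,
    max_reads: int | None = None,
) -> str:
    """Label a cluster by its best-matching library element.

    Library mode: the element with the highest cumulative local-alignment
    score over cluster reads wins; read alignments scoring below
    ``min_score_frac * read_length`` are ignored, and a cluster with no
    passing alignment is "Unknown".  Ties go to the lexicographically first
    element and set ``annotation_tie``.  Truth mode (``truth_elements`` maps
    read_id -> element) labels by majority read origin.
    """
    if truth_elements is not None:
        counts = Counter(
            truth_elements[m] for m in cluster.members if m in truth_elements
        )
        label = counts.most_common(1)[0][0] if counts else "Unknown"
        cluster.annotation = label
        return label
    if not library:
        raise ClusteringError("library must be nonempty")
    aligner = _local_aligner()
    members = cluster.members if max_reads is None else cluster.members[:max_reads]
    scores: dict[str, float] = defaultdict(float)
    for element, consensus in library:
        rc = reverse_complement(consensus)
        for read_id in members:
            seq = reads_by_id[read_id].sequence
            score = max(aligner.score(seq, consensus), aligner.score(seq, rc))
            if score >= min_score_frac * len(seq):
                scores[element] += score
    if not scores:
        cluster.annotation = "Unknown"
        return "Unknown"
    best = max(scores.values())
    winners = sorted(e for e, s in scores.items() if s == best)
    cluster.annotation = winners[0]
    cluster.annotation_tie = len(winners) > 1
    return winners[0]


def comparative_clustering(
    reads_by_origin: Mapping[str, Sequence[ReadRecord]],
    n_per_origin: int,
    origin_b: str,
    origin_0: str,
    rng: np.random.Generator,
    k: int = 17,
    min_identity: float = 0.90,
    min_overlap_frac: float = 0.55,
    pseudocount: float = 1.0,
) -> tuple[list[ReadCluster], int, list[ReadRecord]]:
    """Sample, build the similarity graph, cluster, and score enrichment."""
    sampled = sample_reads(reads_by_origin, n_per_origin, rng)
    edges = similarity_edges(sampled, k, min_identity, min_overlap_frac)
    clusters, singletons = cluster_reads(edges, sampled)
    totals = {origin_b: n_per_origin, origin_0: n_per_origin}
    for cluster in clusters:
        origin_composition(cluster, totals, origin_b, origin_0, pseudocount)
    return clusters, singletons, sampled
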