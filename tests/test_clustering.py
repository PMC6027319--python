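"""Read sampling, similarity graph, components, enrichment, annotation."""

import numpy as np
import pytest

from bchrom import clustering as cl
from bchrom import simulate as sim
from bchrom.io_formats import ReadRecord


def read(rid, seq, origin="0B"):
    return ReadRecord(rid, seq, origin)


@pytest.fixture
def random_reads(rng):
    def make(n, origin, length=100, seed_offset=0):
        local = np.random.default_rng(1000 + seed_offset)
        return [
            read(f"{origin}:{i}", sim.random_sequence(length, 0.5, local), origin)
            for i in range(n)
        ]

    return make


class TestSampling:
    def test_exact_counts_per_origin(self, random_reads, rng):
        pools = {"0B": random_reads(150, "0B"), "2B": random_reads(150, "2B", seed_offset=1)}
        sampled = cl.sample_reads(pools, 100, rng)
        assert len(sampled) == 200
        assert sum(r.origin_label == "0B" for r in sampled) == 100

    def test_deterministic_under_seed(self, random_reads):
        pools = {"0B": random_reads(50, "0B")}
        a = cl.sample_reads(pools, 30, np.random.default_rng(7))
        b = cl.sample_reads(pools, 30, np.random.default_rng(7))
        assert a == b

    def test_insufficient_reads_rejected(self, random_reads, rng):
        with pytest.raises(cl.ClusteringError):
            cl.sample_reads({"0B": random_reads(10, "0B")}, 11, rng)


class TestSimilarityEdges:
    def test_identical_reads_joined(self, rng):
        seq = sim.random_sequence(100, 0.5, rng)
        edges = cl.similarity_edges([read("a", seq), read("b", seq)])
        assert edges == [("a", "b")]

    def test_reverse_complement_joined(self, rng):
        seq = sim.random_sequence(100, 0.5, rng)
        edges = cl.similarity_edges(
            [read("a", seq), read("b", sim.reverse_complement(seq))]
        )
        assert edges == [("a", "b")]

    def test_unrelated_reads_not_joined(self, rng):
        edges = cl.similarity_edges(
            [
                read("a", sim.random_sequence(100, 0.5, rng)),
                read("b", sim.random_sequence(100, 0.5, rng)),
            ]
        )
        assert edges == []

    def test_low_identity_pair_rejected(self, rng):
        """Shared seed k-mer but too many mismatches overall -> no edge."""
        seq = sim.random_sequence(100, 0.5, rng)
        noisy, _ = sim.mutate_sequence(seq, 0.35, 2.0, 0.0, rng)
        # force one shared 17-mer
        noisy = seq[:17] + noisy[17:]
        edges = cl.similarity_edges([read("a", seq), read("b", noisy)])
        assert edges == []

    def test_k_longer_than_read_rejected(self):
        with pytest.raises(cl.ClusteringError):
            cl.similarity_edges([read("a", "ACGT")], k=17)


class TestComponents:
    def test_components_and_singletons(self, random_reads):
        reads = [read(x, s.sequence) for x, s in zip("abcd", random_reads(4, "0B"))]
        clusters, singles = cl.cluster_reads([("a", "b"), ("b", "c")], reads)
        assert len(clusters) == 1 and clusters[0].members == ["a", "b", "c"]
        assert singles == 1

    def test_no_edges_all_singletons(self, random_reads):
        reads = random_reads(5, "0B")
        clusters, singles = cl.cluster_reads([], reads)
        assert clusters == [] and singles == 5

    def test_partition_property(self, rng, random_reads):
        """Every read lands in exactly one cluster or is a singleton."""
        reads = random_reads(40, "0B")
        ids = [r.read_id for r in reads]
        edges = [
            (ids[int(a)], ids[int(b)])
            for a, b in rng.integers(0, 40, size=(30, 2))
            if a != b
        ]
        clusters, singles = cl.cluster_reads(edges, reads)
        clustered = [m for c in clusters for m in c.members]
        assert len(clustered) == len(set(clustered))
        assert len(clustered) + singles == len(reads)
        # numbered by decreasing size
        sizes = [c.size for c in clusters]
        assert sizes == sorted(sizes, reverse=True)


class TestEnrichment:
    def test_symmetric_cluster_is_one(self):
        c = cl.ReadCluster(1, ["a", "b"], {"0B": 5, "2B": 5})
        assert cl.origin_composition(c, {"0B": 100, "2B": 100}, "2B", "0B") == 1.0

    def test_published_cluster_counts_ratio(self):
        """0B=359 vs 2B=23389 at equal totals gives E ~ 65.2."""
        c = cl.ReadCluster(28, [], {"0B": 359, "2B": 23389})
        e = cl.origin_composition(
            c, {"0B": 5_000_000, "2B": 5_000_000}, "2B", "0B", pseudocount=0.0
        )
        assert e == pytest.approx(65.15, abs=0.05)

    def test_pseudocount_keeps_empty_origin_finite(self):
        c = cl.ReadCluster(1, ["a"], {"2B": 10})
        e = cl.origin_composition(c, {"0B": 100, "2B": 100}, "2B", "0B")
        assert np.isfinite(e) and e == pytest.approx(11.0)

    def test_selection_thresholds(self):
        clusters = [
            cl.ReadCluster(1, ["x"] * 60, {"0B": 10, "2B": 50}, enrichment=5.0),
            cl.ReadCluster(2, ["y"] * 60, {"0B": 30, "2B": 30}, enrichment=1.0),
            cl.ReadCluster(3, ["z"] * 10, {"0B": 1, "2B": 9}, enrichment=9.0),
        ]
        report = cl.select_b_clusters(clusters, "2B", "0B", min_size=50,
                                      min_enrichment=3.0)
        assert report["cluster"].tolist() == [1]
        empty = cl.select_b_clusters(clusters, "2B", "0B",
                                     min_enrichment=float("inf"))
        assert empty.empty


class TestAnnotation:
    def test_reads_from_consensus_labeled(self, rng):
        lib = [("X", sim.random_sequence(400, 0.42, rng)),
               ("Y", sim.random_sequence(400, 0.42, rng))]
        reads = {
            f"r{i}": read(f"r{i}", lib[0][1][i * 30 : i * 30 + 100]) for i in range(5)
        }
        c = cl.ReadCluster(1, sorted(reads), {"0B": 5})
        assert cl.annotate_cluster(c, reads, lib) == "X"

    def test_background_reads_unknown(self, rng):
        lib = [("X", sim.random_sequence(400, 0.42, rng))]
        reads = {
            f"r{i}": read(f"r{i}", sim.random_sequence(100, 0.5, rng))
            for i in range(4)
        }
        c = cl.ReadCluster(1, sorted(reads), {"0B": 4})
        assert cl.annotate_cluster(c, reads, lib) == "Unknown"

    def test_tie_flagged_first_label_wins(self, rng):
        seq = sim.random_sequence(400, 0.42, rng)
        lib = [("B2", seq), ("A1", seq)]
        reads = {"r0": read("r0", seq[:100])}
        c = cl.ReadCluster(1, ["r0"], {"0B": 1})
        assert cl.annotate_cluster(c, reads, lib) == "A1"
        assert c.annotation_tie

    def test_truth_mode_majority(self):
        c = cl.ReadCluster(1, ["a", "b", "c"], {"0B": 3})
        label = cl.annotate_cluster(
            c, {}, truth_elements={"a": "X", "b": "X", "c": "Y"}
        )
        assert label == "X"


class TestComparativeRecovery:
    def test_family_reads_form_enriched_cluster(self, rng):
        """Reads from an amplified family cluster together; E tracks dosage."""
        cons = sim.random_sequence(500, 0.42, rng)
        pools = {"0B": [], "2B": []}
        # 0B: 30 family reads + 70 background; 2B: 90 family + 10 background
        for origin, n_fam, offset in (("0B", 30, 0), ("2B", 90, 1)):
            local = np.random.default_rng(50 + offset)
            for i in range(n_fam):
                copy, _ = sim.mutate_sequence(cons, 0.02, 2.0, 0.0, local)
                s = int(local.integers(0, 400))
                pools[origin].append(
                    read(f"{origin}f{i}", copy[s : s + 100], origin)
                )
            for i in range(100 - n_fam):
                pools[origin].append(
                    read(f"{origin}b{i}", sim.random_sequence(100, 0.5, local), origin)
                )
        clusters, singles, sampled = cl.comparative_clustering(
            pools, 100, "2B", "0B", rng
        )
        top = clusters[0]
        assert top.size >= 100
        assert 2.0 < top.enrichment < 4.5  # nominal 3 from 90:30
        assert singles >= 60
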