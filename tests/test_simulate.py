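"""Generator contracts: mutation model, genome assembly, dosage, determinism."""

import numpy as np
import pytest

from bchrom import simulate as sim
from bchrom.landscape import count_substitutions, kimura_divergence


class TestLibraryAndMutation:
    def test_library_lengths_and_determinism(self, tiny_config):
        lib1 = sim.make_family_library(
            tiny_config.families, np.random.default_rng(5)
        )
        lib2 = sim.make_family_library(
            tiny_config.families, np.random.default_rng(5)
        )
        assert lib1 == lib2
        assert [len(s) for _, s in lib1] == [500, 400]

    def test_duplicate_elements_rejected(self, tiny_config, rng):
        specs = (tiny_config.families[0],) * 2
        with pytest.raises(sim.ConfigError):
            sim.make_family_library(specs, rng)

    def test_gc_one_gives_gc_only(self, rng):
        assert set(sim.random_sequence(500, 1.0, rng)) <= {"G", "C"}

    def test_zero_divergence_is_identity(self, rng):
        cons = sim.random_sequence(400, 0.42, rng)
        mut, n_sub = sim.mutate_sequence(cons, 0.0, 2.0, 0.0, rng)
        assert mut == cons and n_sub == 0

    def test_divergence_domain_checked(self, rng):
        with pytest.raises(sim.ConfigError):
            sim.mutate_sequence("ACGT" * 50, 0.6, 2.0, 0.0, rng)

    def test_transition_fraction_matches_kappa(self, rng):
        """Among substitutions at small d, transitions:transversions ~ kappa."""
        kappa, d, n = 2.0, 0.10, 30_000
        cons = sim.random_sequence(n, 0.42, rng)
        mut, _ = sim.mutate_sequence(cons, d, kappa, 0.0, rng)
        ts, tv, cols = count_substitutions(mut, cons, [(0, n)], [(0, n)])
        p_exp, q_exp = sim.k2p_endpoint_probabilities(d, kappa)
        frac_exp = p_exp / (p_exp + q_exp)
        frac = ts / (ts + tv)
        sd = np.sqrt(frac_exp * (1 - frac_exp) / (ts + tv))
        assert abs(frac - frac_exp) < 3 * sd
        # and close to kappa/(kappa+1) at this distance
        assert abs(frac - kappa / (kappa + 1)) < 0.05

    def test_kimura_estimator_recovers_distance(self, rng):
        """K2P estimate of a mutated copy recovers the configured distance."""
        cons = sim.random_sequence(10_000, 0.42, rng)
        mut, _ = sim.mutate_sequence(cons, 0.10, 2.0, 0.0, rng)
        ts, tv, cols = count_substitutions(mut, cons, [(0, 10_000)], [(0, 10_000)])
        k = kimura_divergence(ts / cols, tv / cols)
        assert not k.saturated
        assert abs(k.value - 0.10) < 0.02

    def test_indels_change_length(self, rng):
        cons = sim.random_sequence(2000, 0.42, rng)
        mut, _ = sim.mutate_sequence(cons, 0.05, 2.0, 0.05, rng)
        assert len(mut) != len(cons)


class TestGenomeAssembly:
    def test_truth_annotation_counts_and_conservation(self, tiny_config, rng):
        truth, _ = sim.build_reference_genome(tiny_config, rng)
        by_el = {}
        for iv in truth.annotation:
            by_el.setdefault(iv.element, []).append(iv)
        assert len(by_el["GypsyT"]) == 10
        assert len(by_el["L2T"]) == 8
        assert len(by_el[sim.HPRT_ELEMENT]) == 1
        inserted = sum(iv.length for iv in truth.annotation)
        assert len(truth.sequences["chrA1"]) == (
            tiny_config.background_length + inserted
        )

    def test_intervals_disjoint_and_in_bounds(self, tiny_config, rng):
        truth, _ = sim.build_reference_genome(tiny_config, rng)
        ivs = sorted(truth.annotation, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end < b.start  # spaced, never touching
        assert ivs[-1].end <= len(truth.sequences["chrA1"])

    def test_zero_families_gives_background_plus_hprt(self, rng):
        cfg = sim.SimulationConfig(background_length=20_000)
        truth, _ = sim.build_reference_genome(cfg, rng)
        assert [iv.element for iv in truth.annotation] == [sim.HPRT_ELEMENT]

    def test_overfull_background_rejected(self, rng):
        burst = sim.BurstSpec
        cfg = sim.SimulationConfig(
            background_length=5_000,
            families=(
                sim.TEFamilySpec("X", "f", "DNA", 1000, (burst(0.1, 0.01, 10),)),
            ),
        )
        with pytest.raises(sim.ConfigError, match="background"):
            sim.build_reference_genome(cfg, rng)

    def test_b_haplotype_copies_and_homology_total(self, tiny_config, tiny_truth):
        truth, _ = tiny_truth
        b_ivs = truth.intervals_on("chrB")
        assert sum(iv.element == "GypsyT" for iv in b_ivs) == 40
        assert sum(iv.element == "L2T" for iv in b_ivs) == 0
        for iv in b_ivs:
            key = sim.interval_key(iv)
            homolog = truth.homology[key]
            assert homolog[0] == "chrA1"
            assert homolog[3] == iv.element

    def test_b_haplotype_requires_a_copies(self, rng):
        burst = sim.BurstSpec
        cfg = sim.SimulationConfig(
            background_length=30_000,
            families=(
                sim.TEFamilySpec("X", "f", "DNA", 500, (), b_copies=10),
            ),
        )
        truth, lib = sim.build_reference_genome(cfg, rng)
        with pytest.raises(sim.ConfigError, match="A-complement"):
            sim.build_b_haplotype(truth, cfg, rng, lib)

    def test_seed_determinism_end_to_end(self, tiny_config):
        def run(seed):
            rng = np.random.default_rng(seed)
            truth, lib = sim.build_reference_genome(tiny_config, rng)
            truth = sim.build_b_haplotype(truth, tiny_config, rng, lib)
            sample = tiny_config.samples[2]
            reads, aln = sim.simulate_wgs_sample(truth, sample, tiny_config, rng)
            return truth.sequences, reads, aln

        a, b = run(99), run(99)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]
        c = run(100)
        assert c[0] != a[0]


class TestWgsSampling:
    def test_read_count_poisson_and_no_b_reads(self, tiny_truth, tiny_config, rng):
        truth, _ = tiny_truth
        sample = tiny_config.samples[0]  # 0B
        reads, aln = sim.simulate_wgs_sample(truth, sample, tiny_config, rng)
        expected = (
            tiny_config.mean_depth
            * len(truth.sequences["chrA1"])
            / tiny_config.read_length
        )
        assert abs(len(reads) - expected) < 4 * np.sqrt(expected)
        assert not any(r.read_id.split(":")[1] == "chrB" for r in reads)

    def test_all_mapped_records_on_a_contigs(self, tiny_truth, tiny_config, rng):
        truth, _ = tiny_truth
        sample = tiny_config.samples[2]  # 2B
        _, aln = sim.simulate_wgs_sample(truth, sample, tiny_config, rng)
        assert {a.contig for a in aln if a.is_mapped} == {"chrA1"}

    def test_dosage_law_2b_twice_1b(self, tiny_truth, tiny_config, rng):
        """chrB-origin read counts scale with B dose: 2B draws twice 1B."""
        truth, _ = tiny_truth

        def chrb_reads(sample):
            reads, _ = sim.simulate_wgs_sample(truth, sample, tiny_config, rng)
            return sum(r.read_id.split(":")[1] == "chrB" for r in reads)

        n1 = chrb_reads(tiny_config.samples[1])
        n2 = chrb_reads(tiny_config.samples[2])
        assert abs(n2 - 2 * n1) < 3 * np.sqrt(n2 + 4 * n1)

    def test_b_reads_require_chrb(self, tiny_config, rng):
        truth, _ = sim.build_reference_genome(tiny_config, rng)
        with pytest.raises(sim.ConfigError, match="chrB"):
            sim.simulate_wgs_sample(
                truth, tiny_config.samples[2], tiny_config, rng
            )


class TestExpressionAndCt:
    def test_poisson_limit_at_zero_dispersion(self, rng):
        counts, _ = sim.simulate_expression_counts(
            [(f"e{i}", "DNA") for i in range(800)], 6, [100.0] * 800, 0.0,
            {}, rng,
        )
        values = counts.to_numpy().ravel()
        assert abs(values.var() / values.mean() - 1.0) < 0.08

    def test_nb_variance_exceeds_mean(self, rng):
        counts, _ = sim.simulate_expression_counts(
            [(f"e{i}", "DNA") for i in range(400)], 6, [200.0] * 400, 0.1,
            {}, rng,
        )
        values = counts.to_numpy().ravel()
        # var = mu + phi mu^2 = 200 + 4000
        assert values.var() > 5 * values.mean()

    def test_fold_recovered_in_group_means(self, rng):
        counts, truth = sim.simulate_expression_counts(
            [("de1", "LTR")] * 0 + [("de1", "LTR")], 6, [200.0], 0.1,
            {"de1": 4.0}, rng,
        )
        groups = truth.attrs["groups"]
        b0 = groups.loc[groups["group"] == "B-", "sample_id"]
        b1 = groups.loc[groups["group"] == "B+", "sample_id"]
        ratio = counts[b1].mean(axis=1) / counts[b0].mean(axis=1)
        assert 2.0 < ratio.iloc[0] < 8.0

    def test_truth_labels(self, rng):
        _, truth = sim.simulate_expression_counts(
            [("a", "DNA"), ("b", "LINE")], 3, [50.0, 50.0], 0.05,
            {"b": 0.25}, rng,
        )
        assert truth.set_index("element")["direction"].to_dict() == {
            "a": "ns", "b": "down",
        }

    def test_ct_log2_identities(self, rng):
        table = sim.simulate_ct_values(
            {"x": (2.0, "B-"), "y": (4.0, "B+")}, c0=24.0, noise_sd=0.0,
            rng=rng,
        )
        x = table.set_index("sample_id")
        # target copies == normalizer copies -> delta CT 0
        assert x.loc["x", "ct_target"] == pytest.approx(x.loc["x", "ct_hprt"])
        # doubling copies lowers Ct by exactly one cycle
        assert x.loc["y", "ct_target"] == pytest.approx(
            x.loc["x", "ct_target"] - 1.0
        )

    def test_ct_rejects_nonpositive_copies(self, rng):
        with pytest.raises(sim.ConfigError):
            sim.simulate_ct_values({"x": (0.0, "B-")}, 24.0, 0.0, rng)
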