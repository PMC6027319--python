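"""Depth pileups, HPRT normalization, ratios, expansion sums, dose response."""

import numpy as np
import pandas as pd
import pytest

from bchrom import coverage as cov
from bchrom.io_formats import AlignmentRecord, RepeatInterval


def iv(start, end, element="X", contig="c", family="f", cls="DNA"):
    return RepeatInterval(contig, start, end, element, family, cls)


def aln(pos, cigar="50M", contig="c", flag=0, mapq=60, rid="r"):
    return AlignmentRecord(rid, contig, pos, cigar, mapq, flag)


class TestPileup:
    def test_no_reads_all_zero(self):
        assert cov.pileup_depth([], "c", (0, 10)).tolist() == [0] * 10

    def test_single_perfect_read(self):
        d = cov.pileup_depth([aln(0, "100M")], "c", (0, 100))
        assert d.tolist() == [1] * 100

    def test_overlapping_reads_hand_pileup(self):
        reads = [aln(0, "50M"), aln(25, "50M")]
        d = cov.pileup_depth(reads, "c", (0, 100))
        assert d[:25].tolist() == [1] * 25
        assert d[25:50].tolist() == [2] * 25
        assert d[50:75].tolist() == [1] * 25
        assert d[75:].tolist() == [0] * 25

    def test_cigar_aware_coverage(self):
        # deletions cover the reference, insertions and soft clips do not
        d = cov.pileup_depth([aln(10, "10M5D10M")], "c", (0, 40))
        assert d[10:35].sum() == 25
        d = cov.pileup_depth([aln(10, "5S10M5I10M5S")], "c", (0, 40))
        assert d.sum() == 20 and d[9] == 0 and d[10] == 1

    def test_unmapped_secondary_excluded(self):
        reads = [aln(0, "50M", flag=4), aln(0, "50M", flag=256)]
        assert cov.pileup_depth(reads, "c", (0, 50)).sum() == 0

    def test_mapq_threshold(self):
        reads = [aln(0, "50M", mapq=5)]
        assert cov.pileup_depth(reads, "c", (0, 50), min_mapq=10).sum() == 0
        assert cov.pileup_depth(reads, "c", (0, 50), min_mapq=0).sum() == 50

    def test_span_outside_contig_rejected(self):
        with pytest.raises(cov.CoverageError):
            cov.pileup_depth([], "c", (0, 200), contig_length=100)


class TestIntervalMeanDepth:
    def test_hand_means(self):
        reads = [aln(0, "50M"), aln(25, "50M")]
        assert cov.interval_mean_depth(reads, iv(0, 100)).mean_depth == 1.0
        assert cov.interval_mean_depth(reads, iv(25, 50)).mean_depth == 2.0

    def test_empty_alignments_zero(self):
        assert cov.interval_mean_depth([], iv(10, 20)).mean_depth == 0.0

    def test_matches_batch_table(self, rng):
        reads = [
            aln(int(p), "50M", rid=f"r{k}")
            for k, p in enumerate(rng.integers(0, 500, 300))
        ]
        intervals = [iv(0, 100, "a"), iv(200, 260, "b"), iv(400, 550, "c")]
        table = cov.coverage_table({"s": reads}, intervals)
        for interval in intervals:
            expected = cov.interval_mean_depth(reads, interval).mean_depth
            got = table.xs(interval.element, level="element")["s"].iloc[0]
            assert got == pytest.approx(expected)


class TestNormalization:
    def test_hprt_scale(self):
        assert cov.hprt_scale_factor(10, 10) == 1.0
        assert cov.hprt_scale_factor(20, 10) == 0.5
        with pytest.raises(cov.CoverageError):
            cov.hprt_scale_factor(0, 10)

    @pytest.mark.parametrize(
        "ds,dr,scale,ratio,qualifies",
        [(40, 10, 0.5, 2.0, True), (10, 10, 1.0, 1.0, False),
         (19.99, 10, 1.0, 1.999, False)],
    )
    def test_ratio_and_threshold_boundary(self, ds, dr, scale, ratio, qualifies):
        r = cov.normalized_ratio(ds, dr, scale)
        assert r.ratio == pytest.approx(ratio)
        assert r.qualifies is qualifies

    def test_low_coverage_filter(self):
        depths = pd.Series([1.0, 20.0, 5.0])
        assert cov.filter_low_coverage(depths, 20.0, 0.25).tolist() == [
            False, True, True,
        ]
        # fraction 1.0 retains only loci at >= HPRT depth
        assert cov.filter_low_coverage(depths, 20.0, 1.0).tolist() == [
            False, True, False,
        ]

    def test_normalization_invariant_to_library_scaling(self, rng):
        """Multiplying one sample's depths by c leaves every ratio unchanged."""
        depth = pd.DataFrame(
            {"ref": rng.uniform(10, 30, 20), "s": rng.uniform(10, 80, 20)}
        )
        hprt = {"ref": 20.0, "s": 25.0}
        base = cov.ratio_table(depth, "ref", hprt)
        for c in (0.5, 3.0):
            scaled = depth.copy()
            scaled["s"] = scaled["s"] * c
            got = cov.ratio_table(scaled, "ref", {"ref": 20.0, "s": 25.0 * c})
            assert np.allclose(got["s"], base["s"])


class TestExpansionSummary:
    def _ratios(self, values, element="X"):
        index = pd.MultiIndex.from_tuples(
            [("c", i * 10, i * 10 + 5, element, "f", "DNA") for i in range(len(values))],
            names=["contig", "start", "end", "element", "family", "class_label"],
        )
        return pd.DataFrame({"s": values}, index=index)

    def test_sum_of_excess_over_qualifying_loci(self):
        summary = cov.expansion_summary(self._ratios([2.5, 3.0, 1.2]), ["s"])
        assert summary.loc["X", "s"] == pytest.approx(3.5)
        assert summary.loc["X", "qualifying_loci_s"] == 2

    def test_non_carrier_reports_zero(self):
        summary = cov.expansion_summary(self._ratios([1.0, 0.9, 1.1]), ["s"])
        assert summary.loc["X", "s"] == 0.0

    def test_boundary_locus_at_tau(self):
        summary = cov.expansion_summary(self._ratios([2.0]), ["s"])
        assert summary.loc["X", "s"] == pytest.approx(1.0)

    def test_ratio_sum_mode(self):
        summary = cov.expansion_summary(
            self._ratios([2.5, 3.0, 1.2]), ["s"], sum_mode="ratio"
        )
        assert summary.loc["X", "s"] == pytest.approx(5.5)

    def test_dose_response_and_missing(self):
        summary = pd.DataFrame(
            {"S-1B": [200.0, 0.0], "S-2B": [400.0, 10.0]},
            index=["X", "Y"],
        )
        dr = cov.dose_response(summary, "S-1B", "S-2B")
        assert dr["X"] == pytest.approx(2.0)
        assert np.isnan(dr["Y"])


class TestEndToEndRecovery:
    def test_amplified_element_recovered(self, tiny_truth, tiny_config, rng):
        """Extra copies ~ c_B for 2B and ~ c_B/2 for 1B; nulls report 0."""
        truth, _ = tiny_truth
        from bchrom import simulate as sim

        alignments = {
            s.sample_id: sim.simulate_wgs_sample(truth, s, tiny_config, rng)[1]
            for s in tiny_config.samples
        }
        annotation = [a for a in truth.annotation if a.contig != "chrB"]
        ratios, summary = cov.coverage_analysis(alignments, annotation, "REF-0B")
        assert summary.loc["GypsyT", "S-2B"] == pytest.approx(40, rel=0.25)
        assert summary.loc["GypsyT", "S-1B"] == pytest.approx(20, rel=0.30)
        assert summary.loc["L2T", "S-2B"] == 0.0
        assert summary.loc["L2T", "S-1B"] == 0.0

    def test_requires_single_hprt(self, tiny_truth, tiny_config):
        truth, _ = tiny_truth
        annotation = [
            a for a in truth.annotation
            if a.contig != "chrB" and a.element != "HPRT"
        ]
        with pytest.raises(cov.CoverageError, match="HPRT"):
            cov.coverage_analysis({"REF-0B": []}, annotation, "REF-0B")
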