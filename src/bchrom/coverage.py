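"""Per-locus read depth, HPRT-normalized coverage ratios and expansion sums.

The core statistic: for every annotated TE locus, the mean depth of a test
sample is divided by the reference (0B) sample's depth and rescaled by the
ratio of depths at the single-copy gene HPRT, cancelling library-size
differences.  Loci whose ratio reaches the "at least duplicated" threshold
(tau = 2 by default) qualify, and per element the extra-copy estimate is the
sum of (ratio - 1) over qualifying loci: B-derived reads piling onto their
homologous A loci raise the ratio by the number of extra copies homing there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    RepeatInterval,
    cigar_operations,
    _REF_OPS,
)
from .simulate import HPRT_ELEMENT


class CoverageError(ValueError):
    pass


class CoverageRecord(NamedTuple):
    interval: RepeatInterval
    sample_id: str
    mean_depth: float


@dataclass(frozen=True)
class NormalizedRatio:
    interval: RepeatInterval
    sample_id: str
    ratio: float
    qualifies: bool


def _usable(aln: AlignmentRecord, min_mapq: int) -> bool:
    return aln.is_mapped and aln.is_primary and aln.mapq >= min_mapq


def _reference_blocks(aln: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference spans covered by aligned read bases (deletions cover too)."""
    blocks = []
    pos = aln.pos
    for op, n in cigar_operations(aln.cigar):
        if op in _REF_OPS:
            if op != "N":  # skipped region does not cover
                blocks.append((pos, pos + n))
            pos += n
    return blocks


def pileup_depth(
    alignments: Iterable[AlignmentRecord],
    contig: str,
    span: tuple[int, int],
    min_mapq: int = 0,
    contig_length: int | None = None,
) -> np.ndarray:
    """Per-base depth over ``span`` from primary mapped alignments.

    CIGAR-aware: M/=/X/D consume and cover the reference; insertions and
    soft clips do not.
    """
    start, end = span
    if start < 0 or start >= end:
        raise CoverageError(f"invalid span {span}")
    if contig_length is not None and end > contig_length:
        raise CoverageError(f"span {span} outside contig {contig}")
    diff = np.zeros(end - start + 1, dtype=np.int64)
    for aln in alignments:
        if aln.contig != contig or not _usable(aln, min_mapq):
            continue
        for b1, b2 in _reference_blocks(aln):
            b1, b2 = max(b1, start), min(b2, end)
            if b1 < b2:
                diff[b1 - start] += 1
                diff[b2 - start] -= 1
    return np.cumsum(diff[:-1])


def interval_mean_depth(
    alignments: Iterable[AlignmentRecord],
    interval: RepeatInterval,
    sample_id: str = "",
    min_mapq: int = 0,
) -> CoverageRecord:
    """Mean pileup depth over one annotated interval."""
    if interval.length == 0:
        raise CoverageError("zero-length interval")
    depth = pileup_depth(
        alignments, interval.contig, (interval.start, interval.end), min_mapq
    )
    return CoverageRecord(interval, sample_id, float(depth.mean()))


def coverage_table(
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    intervals: Sequence[RepeatInterval],
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Mean depth for every (locus, sample) in one pass per contig.

    Returns a DataFrame indexed by locus (contig, start, end, element, family,
    class_label) with one column per sample.
    """
    contigs = sorted({iv.contig for iv in intervals})
    index = pd.MultiIndex.from_tuples(
        [
            (iv.contig, iv.start, iv.end, iv.element, iv.family, iv.class_label)
            for iv in intervals
        ],
        names=["contig", "start", "end", "element", "family", "class_label"],
    )
    table = pd.DataFrame(index=index, dtype=float)
    for sample_id, alignments in alignments_by_sample.items():
        means = np.zeros(len(intervals))
        for contig in contigs:
            c_ivs = [(i, iv) for i, iv in enumerate(intervals) if iv.contig == contig]
            length = max(iv.end for _, iv in c_ivs)
            for aln in alignments:
                if aln.contig == contig and _usable(aln, min_mapq):
                    length = max(length, aln.reference_span()[1])
            diff = np.zeros(length + 1, dtype=np.int64)
            for aln in alignments:
                if aln.contig != contig or not _usable(aln, min_mapq):
                    continue
                for b1, b2 in _reference_blocks(aln):
                    diff[b1] += 1
                    diff[b2] -= 1
            depth = np.cumsum(diff[:-1])
            cum = np.concatenate([[0], np.cumsum(depth)])
            for i, iv in c_ivs:
                means[i] = (cum[iv.end] - cum[iv.start]) / iv.length
        table[sample_id] = means
    return table


def hprt_scale_factor(sample_hprt_depth: float, ref_hprt_depth: float) -> float:
    """Library-size normalizer: reference HPRT depth over sample HPRT depth."""
    if sample_hprt_depth <= 0 or ref_hprt_depth <= 0:
        raise CoverageError("HPRT depth must be > 0 in both samples")
    return ref_hprt_depth / sample_hprt_depth


def normalized_ratio(
    depth_sample: float,
    depth_ref: float,
    scale: float,
    tau: float = 2.0,
    interval: RepeatInterval | None = None,
    sample_id: str = "",
) -> NormalizedRatio:
    """HPRT-scaled coverage ratio of a sample locus vs the reference locus."""
    if depth_ref <= 0:
        raise CoverageError("reference depth must pass the low-coverage filter")
    r = (depth_sample / depth_ref) * scale
    return NormalizedRatio(interval, sample_id, r, r >= tau)


def filter_low_coverage(
    ref_depths: pd.Series, hprt_ref_depth: float, fraction: float = 0.25
) -> pd.Series:
    """Boolean mask of loci whose reference depth >= fraction * HPRT depth."""
    if not 0 < fraction <= 1:
        raise CoverageError("fraction must be in (0, 1]")
    return ref_depths >= fraction * hprt_ref_depth


def ratio_table(
    depth_table: pd.DataFrame,
    reference_sample: str,
    hprt_depths: Mapping[str, float],
    tau: float = 2.0,
    min_ref_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-locus normalized ratios for every sample against one reference.

    Loci failing the HPRT low-coverage filter in the reference are dropped
    (their ratios are undefined).  Adds a ``qualifies_<sample>`` flag column
    per sample.
    """
    if reference_sample not in depth_table.columns:
        raise CoverageError(f"reference sample {reference_sample} missing")
    ref = depth_table[reference_sample]
    keep = filter_low_coverage(ref, hprt_depths[reference_sample], min_ref_fraction)
    out = pd.DataFrame(index=depth_table.index[keep])
    for sample in depth_table.columns:
        scale = hprt_scale_factor(hprt_depths[sample], hprt_depths[reference_sample])
        r = (depth_table.loc[keep, sample] / ref[keep]) * scale
        out[sample] = r
        out[f"qualifies_{sample}"] = r >= tau
    return out


def expansion_summary(
    ratios: pd.DataFrame,
    samples: Sequence[str],
    tau: float = 2.0,
    sum_mode: str = "excess",
) -> pd.DataFrame:
    """Per-element extra-copy estimate: sum over qualifying loci.

    ``sum_mode='excess'`` sums (r - 1) per qualifying locus (the default
    reading: a non-carrier reports 0.00); ``sum_mode='ratio'`` sums r itself.
    Returns elements x samples with a ``qualifying_loci_<sample>`` column per
    sample.
    """
    if sum_mode not in {"excess", "ratio"}:
        raise CoverageError(f"unknown sum_mode {sum_mode!r}")
    elements = ratios.index.get_level_values("element")
    rows = {}
    for sample in samples:
        r = ratios[sample]
        qual = r >= tau
        contrib = (r - 1.0) if sum_mode == "excess" else r
        contrib = contrib.where(qual, 0.0)
        grouped = contrib.groupby(elements).sum()
        counts = qual.groupby(elements).sum()
        rows[sample] = grouped
        rows[f"qualifying_loci_{sample}"] = counts
    out = pd.DataFrame(rows)
    out.index.name = "element"
    return out


def dose_response(
    summary: pd.DataFrame, sample_1b: str, sample_2b: str
) -> pd.Series:
    """Per-element 2B:1B extra-copy ratio; NaN where the 1B sum is zero."""
    one = summary[sample_1b]
    two = summary[sample_2b]
    return (two / one.where(one > 0)).rename("dose_response")


def coverage_analysis(
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    annotation: Sequence[RepeatInterval],
    reference_sample: str,
    tau: float = 2.0,
    min_ref_fraction: float = 0.25,
    min_mapq: int = 0,
    sum_mode: str = "excess",
    exclude_simple: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end per-locus ratios and per-element expansion table.

    The annotation must contain exactly one HPRT interval, which anchors the
    normalization and is excluded from the ratio table itself.
    """
    hprt_ivs = [iv for iv in annotation if iv.element == HPRT_ELEMENT]
    if len(hprt_ivs) != 1:
        raise CoverageError("annotation must contain exactly one HPRT interval")
    hprt = hprt_ivs[0]
    te_ivs = [
        iv
        for iv in annotation
        if iv.element != HPRT_ELEMENT
        and not (
            exclude_simple
            and iv.class_label in {"Simple_repeat", "Low_complexity"}
        )
    ]
    depth = coverage_table(
        alignments_by_sample, list(te_ivs) + [hprt], min_mapq=min_mapq
    )
    hprt_row = depth.xs(HPRT_ELEMENT, level="element")
    hprt_depths = {s: float(hprt_row[s].iloc[0]) for s in depth.columns}
    te_depth = depth[depth.index.get_level_values("element") != HPRT_ELEMENT]
    ratios = ratio_table(
        te_depth, reference_sample, hprt_depths, tau, min_ref_fraction
    )
    samples = [s for s in alignments_by_sample if s != reference_sample]
    summary = expansion_summary(ratios, samples, tau, sum_mode)
    return ratios, summary
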