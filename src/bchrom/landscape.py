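"""Kimura two-parameter divergence of repeat copies and the repeat landscape.

Each annotated copy is globally aligned to its family consensus; transition
and transversion fractions per ungapped column give the K2P distance
K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q)).  Binning masked base pairs by
divergence yields the repeat landscape, whose peaks mark insertion waves
(bursts) of element activity: low divergence means recent insertion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.signal import find_peaks

from .io_formats import RepeatInterval
from .simulate import reverse_complement

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class LandscapeError(ValueError):
    pass


@dataclass(frozen=True)
class CopyAlignment:
    """Substitution summary of one copy aligned to its consensus."""

    element: str
    interval: RepeatInterval | None
    p: float  # transition fraction per ungapped column
    q: float  # transversion fraction per ungapped column
    aligned_columns: int

    def __post_init__(self) -> None:
        if self.aligned_columns <= 0:
            raise LandscapeError("alignment has no usable columns")
        if self.p < 0 or self.q < 0 or self.p + self.q > 1 + 1e-12:
            raise LandscapeError(f"invalid fractions p={self.p}, q={self.q}")


class KimuraResult(NamedTuple):
    value: float
    saturated: bool


class CopyDivergence(NamedTuple):
    element: str
    family: str
    length_bp: int
    divergence: float
    saturated: bool


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def count_substitutions(
    seq_a: str,
    seq_b: str,
    blocks_a: Sequence[tuple[int, int]],
    blocks_b: Sequence[tuple[int, int]],
    cpg_adjust: bool = False,
) -> tuple[float, float, int]:
    """(transitions, transversions, ungapped columns) over aligned blocks.

    Columns containing N in either sequence are excluded entirely.  With
    ``cpg_adjust``, a transition whose consensus (seq_b) base sits in a CpG
    dinucleotide counts as 1/10 of a transition — the usual correction for
    hypermutable methylated CpG sites.
    """
    transitions = 0.0
    transversions = 0.0
    columns = 0
    for (a1, a2), (b1, b2) in zip(blocks_a, blocks_b):
        for i, j in zip(range(a1, a2), range(b1, b2)):
            x, y = seq_a[i], seq_b[j]
            if x == "N" or y == "N":
                continue
            columns += 1
            if x == y:
                continue
            if _is_transition(x, y):
                in_cpg = cpg_adjust and (
                    (y == "C" and j + 1 < len(seq_b) and seq_b[j + 1] == "G")
                    or (y == "G" and j > 0 and seq_b[j - 1] == "C")
                )
                transitions += 0.1 if in_cpg else 1.0
            else:
                transversions += 1.0
    return transitions, transversions, columns


def align_to_consensus(
    copy_seq: str,
    consensus_seq: str,
    element: str = "",
    interval: RepeatInterval | None = None,
    cpg_adjust: bool = False,
) -> CopyAlignment:
    """Global affine alignment of a copy against its consensus.

    Copies annotated on the minus strand must be reverse-complemented by the
    caller (see :func:`genome_copy_divergences`).  Gap columns are excluded
    from the substitution-fraction denominators.
    """
    if not copy_seq or not consensus_seq:
        raise LandscapeError("empty sequence")
    alignment = next(iter(_aligner().align(copy_seq, consensus_seq)))
    blocks_a, blocks_b = alignment.aligned
    ts, tv, columns = count_substitutions(
        copy_seq, consensus_seq, blocks_a, blocks_b, cpg_adjust
    )
    if columns == 0:
        raise LandscapeError("no usable (non-N, ungapped) columns")
    return CopyAlignment(
        element=element,
        interval=interval,
        p=ts / columns,
        q=tv / columns,
        aligned_columns=columns,
    )


def substitution_fractions(alignment: CopyAlignment) -> tuple[float, float]:
    return alignment.p, alignment.q


def kimura_divergence(p: float, q: float) -> KimuraResult:
    """K2P distance; saturated (capped at 0.50) outside the formula's domain."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return KimuraResult(0.5, True)
    return KimuraResult(-0.5 * math.log(w1 * math.sqrt(w2)), False)


def copy_divergence(
    copy_seq: str,
    consensus_seq: str,
    element: str = "",
    family: str = "",
    cpg_adjust: bool = False,
) -> CopyDivergence:
    aln = align_to_consensus(copy_seq, consensus_seq, element, cpg_adjust=cpg_adjust)
    k = kimura_divergence(aln.p, aln.q)
    return CopyDivergence(element, family, len(copy_seq), k.value, k.saturated)


def genome_copy_divergences(
    sequences: dict[str, str],
    annotation: Iterable[RepeatInterval],
    library: dict[str, str],
    cpg_adjust: bool = False,
    contigs: Sequence[str] | None = None,
) -> list[CopyDivergence]:
    """Divergence of every annotated copy with a consensus in the library.

    Minus-strand copies are reverse-complemented before alignment.  Intervals
    whose element is absent from the library (e.g. the HPRT anchor) are
    skipped.
    """
    out = []
    for iv in annotation:
        if iv.element not in library:
            continue
        if contigs is not None and iv.contig not in contigs:
            continue
        seq = sequences[iv.contig][iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        aln = align_to_consensus(seq, library[iv.element], iv.element, iv, cpg_adjust)
        k = kimura_divergence(aln.p, aln.q)
        out.append(CopyDivergence(iv.element, iv.family, iv.length, k.value, k.saturated))
    return out


def build_landscape(
    divergences: Iterable[CopyDivergence],
    bin_width: float = 1.0,
    genome_size: int | None = None,
    max_divergence: float = 0.5,
) -> pd.DataFrame:
    """Masked bp per (divergence bin x family).

    Each copy contributes its length to the bin floor(100*K / bin_width) of
    its family.  Saturated copies are excluded (they have no reliable
    divergence).  Columns: one per family, index: bin lower edge in percent;
    with ``genome_size`` a parallel ``pct_<family>`` scaling is NOT added —
    use :func:`landscape_long` for the tidy per-bin output.
    """
    if bin_width <= 0:
        raise LandscapeError("bin_width must be > 0")
    n_bins = int(math.ceil(100.0 * max_divergence / bin_width))
    edges = np.arange(n_bins) * bin_width
    families = sorted({d.family for d in divergences})
    matrix = pd.DataFrame(0.0, index=edges, columns=families)
    matrix.index.name = "divergence_pct"
    for d in divergences:
        if d.saturated:
            continue
        if d.divergence < 0:
            raise LandscapeError("negative divergence")
        b = min(int(100.0 * d.divergence // bin_width), n_bins - 1)
        matrix.loc[edges[b], d.family] += d.length_bp
    if genome_size is not None:
        matrix.attrs["genome_size"] = genome_size
    return matrix


def landscape_long(matrix: pd.DataFrame, genome_size: int | None = None) -> pd.DataFrame:
    """Tidy (bin, family, bp, pct-of-genome) table for writing to TSV."""
    genome_size = genome_size or matrix.attrs.get("genome_size")
    long = matrix.stack().rename("bp").reset_index()
    long.columns = ["divergence_pct", "family", "bp"]
    if genome_size:
        long["pct_genome"] = long["bp"] / genome_size * 100.0
    return long


def detect_bursts(
    matrix: pd.DataFrame, min_prominence_frac: float = 0.10
) -> list[float]:
    """Divergence-bin positions of insertion-wave peaks.

    The per-bin totals (summed over families) are smoothed with a 3-bin
    moving average; local maxima with prominence >= min_prominence_frac of
    the global smoothed maximum are reported in divergence order.
    """
    total = matrix.sum(axis=1).to_numpy(dtype=float)
    if total.max() <= 0:
        return []
    smooth = np.convolve(total, np.ones(3) / 3.0, mode="same")
    # pad so peaks in the first/last bin are still local maxima
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence_frac * smooth.max())
    return [float(matrix.index[i - 1]) for i in peaks]


def plot_landscape(matrix: pd.DataFrame, path: str, genome_size: int | None = None):
    """Stacked-bar repeat landscape (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.copy()
    ylabel = "masked bp"
    genome_size = genome_size or matrix.attrs.get("genome_size")
    if genome_size:
        data = data / genome_size * 100.0
        ylabel = "% of genome"
    fig, ax = plt.subplots(figsize=(9, 4))
    bottom = np.zeros(len(data))
    for family in data.columns:
        ax.bar(data.index, data[family], width=0.9, bottom=bottom, label=family)
        bottom += data[family].to_numpy()
    ax.set_xlabel("Kimura divergence from consensus (%)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
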