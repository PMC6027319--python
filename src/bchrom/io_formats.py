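"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  SAM and RepeatMasker ``.out``
files are 1-based on disk; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Controlled vocabulary for repeat classes.  RepeatMasker classes outside this
#: set (rRNA, snRNA, ...) are mapped to "Unknown".
REPEAT_CLASSES = frozenset(
    {
        "DNA",
        "LINE",
        "LTR",
        "SINE",
        "RC",
        "Satellite",
        "Simple_repeat",
        "Low_complexity",
        "Unknown",
    }
)

#: Classes counted as retroelements (RNA-intermediate transposons).
RETROELEMENT_CLASSES = frozenset({"LINE", "LTR", "SINE"})


class FormatError(ValueError):
    """A file did not follow its declared dialect."""


@dataclass(frozen=True)
class RepeatInterval:
    """One annotated repeat locus on the reference (0-based half-open)."""

    contig: str
    start: int
    end: int
    element: str
    family: str
    class_label: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.class_label not in REPEAT_CLASSES:
            raise FormatError(f"unknown repeat class {self.class_label!r}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read tagged with the sample it came from."""

    read_id: str
    sequence: str
    origin_label: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"empty sequence for read {self.read_id}")


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# ops consuming reference / read bases
_REF_OPS = frozenset("MDN=X")
_READ_OPS = frozenset("MIS=X")


def cigar_operations(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) runs."""
    if cigar in {"", "*"}:
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if sum(n for _, n in ops) == 0 or "".join(
        f"{n}{op}" for op, n in ops
    ) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return ops


@dataclass(frozen=True)
class AlignmentRecord:
    """A single read alignment (0-based leftmost position)."""

    read_id: str
    contig: str
    pos: int
    cigar: str
    mapq: int = 0
    flag: int = 0

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_primary(self) -> bool:
        return not self.flag & 0x900

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    def reference_span(self) -> tuple[int, int]:
        """[start, end) of reference bases consumed by the alignment."""
        length = sum(n for op, n in cigar_operations(self.cigar) if op in _REF_OPS)
        return self.pos, self.pos + length

    def read_length(self) -> int:
        return sum(n for op, n in cigar_operations(self.cigar) if op in _READ_OPS)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (identifier, uppercased sequence) pairs."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            return []
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path, origin_label: str = "") -> list[ReadRecord]:
    """Read 4-line FASTQ records, tagging each read with an origin label."""
    return [
        ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            origin_label=origin_label,
            quality="".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            ),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def filter_reads_by_quality(
    reads: Iterable[ReadRecord], min_phred: int = 28, min_fraction: float = 0.8
) -> list[ReadRecord]:
    """Keep reads where >= ``min_fraction`` of bases have Phred >= ``min_phred``.

    Both comparisons are inclusive; reads without quality strings are kept.
    """
    kept = []
    for read in reads:
        if read.quality is None:
            kept.append(read)
            continue
        good = sum(1 for c in read.quality if ord(c) - 33 >= min_phred)
        if good >= min_fraction * len(read.quality):
            kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _split_class_family(token: str) -> tuple[str, str]:
    if "/" in token:
        cls, family = token.split("/", 1)
    else:
        cls, family = token, token
    if cls.rstrip("?") in REPEAT_CLASSES:
        cls = cls.rstrip("?")
    else:
        cls = "Unknown"
    return cls, family


def parse_repeatmasker_out(
    path: str | Path, exclude_simple: bool = False
) -> list[RepeatInterval]:
    """Parse the standard RepeatMasker ``.out`` table.

    The file carries 3 header lines and whitespace-separated columns with
    1-based inclusive coordinates; ``start`` is converted to 0-based here.
    With ``exclude_simple``, Simple_repeat and Low_complexity rows are dropped.
    """
    intervals: list[RepeatInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: too few columns")
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable coordinates {fields[5]!r}/{fields[6]!r}"
                ) from exc
            strand = "-" if fields[8] == "C" else "+"
            cls, family = _split_class_family(fields[10])
            if exclude_simple and cls in {"Simple_repeat", "Low_complexity"}:
                continue
            intervals.append(
                RepeatInterval(
                    contig=fields[4],
                    start=begin - 1,
                    end=end,
                    element=fields[9],
                    family=family,
                    class_label=cls,
                    strand=strand,
                )
            )
    return intervals


# ---------------------------------------------------------------------------
# SAM (plain-text dialect; convert BAM/CRAM externally with samtools view -h)
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a plain SAM file into AlignmentRecords (POS converted to 0-based)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        try:
            alignments = list(sam.fetch(until_eof=True))
        except (OSError, ValueError) as exc:
            raise FormatError(f"{path}: malformed SAM record ({exc})") from exc
        for aln in alignments:
            cigar = aln.cigarstring or "*"
            if aln.query_sequence and cigar != "*":
                consumed = sum(
                    n
                    for op, n in cigar_operations(cigar)
                    if op in _READ_OPS and op != "H"
                )
                if consumed != len(aln.query_sequence):
                    raise FormatError(
                        f"CIGAR {cigar} does not consume read {aln.query_name} "
                        f"({consumed} vs {len(aln.query_sequence)} bases)"
                    )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig=aln.reference_name if not aln.is_unmapped else "*",
                    pos=aln.reference_start if not aln.is_unmapped else 0,
                    cigar=cigar,
                    mapq=aln.mapping_quality,
                    flag=aln.flag,
                )
            )
    return records


def sam_contig_lengths(path: str | Path) -> dict[str, int]:
    """Contig lengths from the @SQ header lines of a SAM file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return dict(zip(sam.references, sam.lengths))


def write_sam(
    records: Sequence[AlignmentRecord],
    header: dict[str, int],
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write records to plain SAM (POS re-converted to 1-based).

    ``header`` maps contig name -> length; ``sequences`` optionally maps
    read_id -> read sequence (written as '*' when absent).
    """
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig, length in header.items():
            out.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for rec in records:
            seq = sequences.get(rec.read_id, "*") if sequences else "*"
            qual = "*" if seq == "*" else "I" * len(seq)
            contig = rec.contig if rec.is_mapped else "*"
            pos = rec.pos + 1 if rec.is_mapped else 0
            out.write(
                f"{rec.read_id}\t{rec.flag}\t{contig}\t{pos}\t{rec.mapq}\t"
                f"{rec.cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )


# ---------------------------------------------------------------------------
# BED and TSV tables
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["contig", "start", "end", "element", "family", "class_label", "strand"]


def read_bed(path: str | Path) -> list[RepeatInterval]:
    """Read BED (0-based half-open) with element/family/class/strand columns."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            intervals.append(
                RepeatInterval(
                    contig=fields[0],
                    start=start,
                    end=end,
                    element=fields[3],
                    family=fields[4],
                    class_label=fields[5],
                    strand=fields[6],
                )
            )
    return intervals


def write_bed(intervals: Iterable[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.element}\t"
                f"{iv.family}\t{iv.class_label}\t{iv.strand}\n"
            )


def read_tsv_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with a header row."""
    return pd.read_csv(path, sep="\t")


def write_tsv_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
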