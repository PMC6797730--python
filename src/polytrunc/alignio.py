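"""Alignment and sequence I/O.

Normalizes SAM records (via :mod:`pysam`) and the package's plain-text
truth-alignment TSV into a single in-memory representation,
:class:`TranscriptAlignment`, and applies the standard long-read
quantification filters: drop secondary and supplementary alignments and
drop reads aligned on less than 80% of their full length.

Coordinates are 0-based half-open throughout; SAM's 1-based POS is
converted on ingest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "TranscriptRecord",
    "TranscriptAlignment",
    "AlignmentSet",
    "UnmappedReadError",
    "parse_alignment",
    "filter_alignments",
    "read_sam",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_transcript_metadata",
    "write_transcript_metadata",
]

MIN_QUERY_FRACTION = 0.80

_SAM_FLAG_REVERSE = 0x10
_SAM_FLAG_SECONDARY = 0x100
_SAM_FLAG_SUPPLEMENTARY = 0x800

# CIGAR op codes (pysam numeric encoding)
_OPS_QUERY = frozenset({0, 1, 4, 7, 8})        # M, I, S, =, X consume query
_OPS_REF = frozenset({0, 2, 3, 7, 8})          # M, D, N, =, X consume reference
_OPS_ALIGNED_QUERY = frozenset({0, 1, 7, 8})   # M, I, =, X: query bases explained


class UnmappedReadError(ValueError):
    """Raised when an unmapped SAM record is passed where a mapped one is required."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A spliced transcript sequence (5'->3' mRNA sense) with its metadata."""

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptAlignment:
    """One read aligned to one target (transcript or genome contig).

    ``query_length`` is the full read length including soft- and
    hard-clipped bases; ``query_span`` is the number of query bases in
    aligned operations (M/=/X/I), so ``aligned_query_fraction`` measures
    the portion of the molecule the alignment explains.
    """

    read_id: str
    target_id: str
    target_start: int
    target_end: int
    query_length: int
    query_span: int
    is_secondary: bool = False
    is_supplementary: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.target_start < self.target_end:
            raise ValueError(
                f"invalid target interval [{self.target_start},{self.target_end}) "
                f"for read {self.read_id!r}"
            )
        if self.query_length <= 0 or not 0 <= self.query_span <= self.query_length:
            raise ValueError(f"invalid query span/length for read {self.read_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.is_secondary and self.is_supplementary:
            raise ValueError("an alignment cannot be both secondary and supplementary")

    @property
    def is_primary(self) -> bool:
        return not self.is_secondary

    @property
    def aligned_query_fraction(self) -> float:
        return self.query_span / self.query_length

    @property
    def sam_flag(self) -> int:
        flag = 0
        if self.strand == "-":
            flag |= _SAM_FLAG_REVERSE
        if self.is_secondary:
            flag |= _SAM_FLAG_SECONDARY
        if self.is_supplementary:
            flag |= _SAM_FLAG_SUPPLEMENTARY
        return flag


@dataclass(frozen=True)
class AlignmentSet:
    """An ordered collection of alignments sharing one target space."""

    alignments: tuple[TranscriptAlignment, ...]
    target_space: str = "transcriptome"

    def __post_init__(self) -> None:
        if self.target_space not in ("transcriptome", "genome"):
            raise ValueError(f"unknown target space {self.target_space!r}")
        object.__setattr__(self, "alignments", tuple(self.alignments))

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self) -> Iterator[TranscriptAlignment]:
        return iter(self.alignments)

    def by_target(self) -> dict[str, list[TranscriptAlignment]]:
        grouped: dict[str, list[TranscriptAlignment]] = {}
        for aln in self.alignments:
            grouped.setdefault(aln.target_id, []).append(aln)
        return grouped


def parse_alignment(record: pysam.AlignedSegment) -> TranscriptAlignment:
    """Normalize one mapped SAM record.

    ``target_start``/``target_end`` come from POS plus the
    reference-consuming CIGAR length; ``query_length`` is inferred from
    the CIGAR and includes hard clips. Unmapped records raise
    :class:`UnmappedReadError`; a mapped record without a CIGAR raises
    :class:`ValueError`.
    """
    if record.is_unmapped:
        raise UnmappedReadError(f"read {record.query_name!r} is unmapped")
    cigar = record.cigartuples
    if not cigar:
        raise ValueError(f"read {record.query_name!r} has no CIGAR")
    hard_clipped = sum(length for op, length in cigar if op == 5)
    if record.query_sequence:
        # full read length = stored sequence plus hard-clipped bases
        query_length = len(record.query_sequence) + hard_clipped
    else:
        query_length = (
            sum(length for op, length in cigar if op in _OPS_QUERY) + hard_clipped
        )
    query_span = sum(length for op, length in cigar if op in _OPS_ALIGNED_QUERY)
    ref_span = sum(length for op, length in cigar if op in _OPS_REF)
    return TranscriptAlignment(
        read_id=record.query_name,
        target_id=record.reference_name,
        target_start=record.reference_start,
        target_end=record.reference_start + ref_span,
        query_length=query_length,
        query_span=query_span,
        is_secondary=record.is_secondary,
        is_supplementary=record.is_supplementary,
        strand="-" if record.is_reverse else "+",
    )


def read_sam(path: str, target_space: str = "transcriptome") -> AlignmentSet:
    """Read all mapped records of a SAM/BAM file into an :class:`AlignmentSet`.

    Unmapped records are skipped (they carry no interval to analyze).
    """
    alignments: list[TranscriptAlignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for record in fh:
            if record.is_unmapped:
                continue
            alignments.append(parse_alignment(record))
    return AlignmentSet(tuple(alignments), target_space=target_space)


def filter_alignments(
    aset: AlignmentSet, min_query_fraction: float = MIN_QUERY_FRACTION
) -> AlignmentSet:
    """Apply the long-read quantification filters.

    Keeps primary, non-supplementary alignments whose aligned query
    fraction is at least ``min_query_fraction`` (reads aligned on *less*
    than that share of their length are removed, so the boundary value
    is retained). Order is preserved; the input is untouched.
    """
    kept = tuple(
        aln
        for aln in aset
        if aln.is_primary
        and not aln.is_supplementary
        and aln.aligned_query_fraction >= min_query_fraction
    )
    return AlignmentSet(kept, target_space=aset.target_space)


# ---------------------------------------------------------------------------
# Truth-alignment TSV dialect
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = (
    "read_id",
    "target_id",
    "target_start",
    "target_end",
    "query_length",
    "query_span",
    "flags",
    "strand",
)


def write_truth_tsv(aset: AlignmentSet, path: str) -> None:
    """Write alignments as a plain TSV (the simulator's SAM-free path)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for aln in aset:
            writer.writerow(
                (
                    aln.read_id,
                    aln.target_id,
                    aln.target_start,
                    aln.target_end,
                    aln.query_length,
                    aln.query_span,
                    aln.sam_flag,
                    aln.strand,
                )
            )


def read_truth_tsv(path: str, target_space: str = "transcriptome") -> AlignmentSet:
    alignments: list[TranscriptAlignment] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TRUTH_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"truth TSV {path!r} missing columns: {sorted(missing)}")
        for row in reader:
            flags = int(row["flags"])
            alignments.append(
                TranscriptAlignment(
                    read_id=row["read_id"],
                    target_id=row["target_id"],
                    target_start=int(row["target_start"]),
                    target_end=int(row["target_end"]),
                    query_length=int(row["query_length"]),
                    query_span=int(row["query_span"]),
                    is_secondary=bool(flags & _SAM_FLAG_SECONDARY),
                    is_supplementary=bool(flags & _SAM_FLAG_SUPPLEMENTARY),
                    strand=row["strand"],
                )
            )
    return AlignmentSet(tuple(alignments), target_space=target_space)


def read_alignments(path: str, target_space: str = "transcriptome") -> AlignmentSet:
    """Dispatch on file type: ``.sam``/``.bam`` via pysam, else truth TSV."""
    lower = path.lower()
    if lower.endswith((".sam", ".bam")):
        return read_sam(path, target_space=target_space)
    return read_truth_tsv(path, target_space=target_space)


# ---------------------------------------------------------------------------
# Sequences and metadata
# ---------------------------------------------------------------------------


def read_fasta(
    path: str, metadata: Mapping[str, tuple[str, str]] | None = None
) -> list[TranscriptRecord]:
    """Read transcript sequences from FASTA.

    ``metadata`` maps transcript_id -> (gene_id, biotype); sequences
    without an entry get a one-transcript gene of the same id and the
    ``protein_coding`` biotype.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            if entry.name in seen:
                raise ValueError(f"duplicate transcript id {entry.name!r} in {path!r}")
            seen.add(entry.name)
            gene_id, biotype = (
                metadata.get(entry.name, (entry.name, "protein_coding"))
                if metadata is not None
                else (entry.name, "protein_coding")
            )
            records.append(
                TranscriptRecord(
                    transcript_id=entry.name,
                    gene_id=gene_id,
                    biotype=biotype,
                    sequence=entry.sequence.upper(),
                )
            )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable, path: str) -> None:
    """Write (read_id, sequence, quality) triples or objects with those attributes."""
    with open(path, "w") as fh:
        for read in reads:
            if isinstance(read, tuple):
                read_id, sequence, quality = read
            else:
                read_id, sequence, quality = read.read_id, read.sequence, read.quality
            fh.write(f"@{read_id}\n{sequence}\n+\n{quality}\n")


def read_transcript_metadata(path: str) -> dict[str, tuple[str, str]]:
    """Read a transcript metadata TSV (transcript_id, gene_id, biotype[, length])."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"transcript_id", "gene_id", "biotype"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"metadata TSV {path!r} missing columns: {sorted(missing)}")
        for row in reader:
            out[row["transcript_id"]] = (row["gene_id"], row["biotype"])
    return out


def write_transcript_metadata(records: Iterable[TranscriptRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("transcript_id", "gene_id", "biotype", "length"))
        for rec in records:
            writer.writerow((rec.transcript_id, rec.gene_id, rec.biotype, rec.length))
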