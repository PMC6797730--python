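"""Sequence- and annotation-level feature extraction.

Three independent feature extractors live here:

* maximal internal homopolymer runs of A or T on transcripts — the
  anchors of the cDNA truncation-bias statistic;
* exonic transposable-element (TE) coverage of genes, from exon and
  repeat intervals;
* splice-site dinucleotide classification (canonical GT..AG) from
  genomic intron coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

__all__ = [
    "HomopolymerRun",
    "IntronCall",
    "find_homopolymer_runs",
    "select_analysis_run",
    "exonic_te_fraction",
    "classify_intron_dinucleotides",
    "te_category",
    "TE_CATEGORY_LABELS",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Exonic TE-coverage classes for the long- vs short-read quantification
# ratio analysis: genes with no exonic TE, then thirds of coverage.
TE_CATEGORY_LABELS = ("0%", ">0-33%", ">33-66%", ">66-100%")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one base on a transcript, 0-based half-open."""

    transcript_id: str
    base: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty homopolymer run")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronCall:
    """Donor/acceptor dinucleotides of one intron, read on its strand."""

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    donor_dinuc: str
    acceptor_dinuc: str
    canonical: bool


def find_homopolymer_runs(record, base: str, min_length: int) -> list[HomopolymerRun]:
    """All maximal runs of ``base`` with length >= ``min_length``, 5'->3'.

    ``record`` may be a :class:`~polytrunc.alignio.TranscriptRecord` or any
    object with ``transcript_id`` and ``sequence``. N never extends a run.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if base not in ("A", "T"):
        raise ValueError(f"run base must be 'A' or 'T', got {base!r}")
    runs: list[HomopolymerRun] = []
    pos = 0
    for char, group in groupby(record.sequence):
        length = sum(1 for _ in group)
        if char == base and length >= min_length:
            runs.append(HomopolymerRun(record.transcript_id, base, pos, pos + length))
        pos += length
    return runs


def select_analysis_run(
    record, runs: Sequence[HomopolymerRun], flank: int = 100
) -> HomopolymerRun | None:
    """Pick the one run per transcript used for the bias profile.

    Only runs with at least ``flank`` nt on both sides qualify, so every
    offset position up to ``flank`` exists on the transcript. Among
    qualifying runs the longest wins; ties go to the 5'-most.
    """
    length = record.length if hasattr(record, "length") else len(record.sequence)
    candidates = [
        run for run in runs if run.start >= flank and run.end <= length - flank
    ]
    for run in candidates:
        if run.transcript_id != record.transcript_id:
            raise ValueError(
                f"run on {run.transcript_id!r} does not belong to "
                f"{record.transcript_id!r}"
            )
    if not candidates:
        return None
    return max(candidates, key=lambda run: (run.length, -run.start))


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals as a sorted disjoint list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted((s, e) for s, e in intervals if e > s):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersection_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def exonic_te_fraction(
    exons: Sequence[tuple[int, int]], repeats: Sequence[tuple[int, int]]
) -> float:
    """Fraction of a gene's exonic bases covered by repeats.

    Both inputs are 0-based half-open intervals on one coordinate
    system; union semantics on both sides, so overlap and order of the
    inputs do not matter.
    """
    exon_union = _merge_intervals(exons)
    if not exon_union:
        raise ValueError("a gene must have at least one non-empty exon")
    exon_len = sum(end - start for start, end in exon_union)
    inter = _intersection_length(exon_union, _merge_intervals(repeats))
    return inter / exon_len


def te_category(fraction: float) -> str:
    """Bin an exonic TE fraction into the four coverage classes."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"TE fraction must be in [0,1], got {fraction}")
    if fraction == 0.0:
        return TE_CATEGORY_LABELS[0]
    if fraction <= 1 / 3:
        return TE_CATEGORY_LABELS[1]
    if fraction <= 2 / 3:
        return TE_CATEGORY_LABELS[2]
    return TE_CATEGORY_LABELS[3]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    if not isinstance(seq, str):  # pyfaidx returns a Sequence object
        seq = str(seq)
    return seq.upper()


def classify_intron_dinucleotides(
    genome,
    introns: Sequence[tuple[str, int, int, str]],
    accept_reverse: bool = False,
) -> tuple[list[IntronCall], float]:
    """Classify introns as canonical GT..AG and return the canonical fraction.

    Each intron is (chrom, start, end, strand) with 0-based half-open
    genomic coordinates of the intronic bases. The donor dinucleotide is
    the first two intronic bases and the acceptor the last two, read on
    the annotated strand. With ``accept_reverse`` (appropriate for
    unstranded cDNA reads) an intron whose opposite strand reads GT..AG
    (CT..AC on the forward strand) also counts as canonical. Introns
    shorter than 4 nt are counted as non-canonical.
    """
    calls: list[IntronCall] = []
    n_canonical = 0
    for chrom, start, end, strand in introns:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        too_short = end - start < 4
        left = _fetch(genome, chrom, start, min(start + 2, end))
        right = _fetch(genome, chrom, max(end - 2, start), end)
        if strand == "+":
            donor, acceptor = left, right
            donor_pos, acceptor_pos = start, end - 2
        else:
            donor, acceptor = reverse_complement(right), reverse_complement(left)
            donor_pos, acceptor_pos = end - 2, start
        canonical = not too_short and donor == "GT" and acceptor == "AG"
        if accept_reverse and not canonical and not too_short:
            # same intron read from the opposite strand
            if strand == "+":
                rev_donor = reverse_complement(right)
                rev_acceptor = reverse_complement(left)
            else:
                rev_donor, rev_acceptor = left, right
            canonical = rev_donor == "GT" and rev_acceptor == "AG"
        calls.append(
            IntronCall(
                chrom=chrom,
                donor_pos=donor_pos,
                acceptor_pos=acceptor_pos,
                strand=strand,
                donor_dinuc=donor,
                acceptor_dinuc=acceptor,
                canonical=canonical,
            )
        )
        n_canonical += canonical
    fraction = n_canonical / len(calls) if calls else 0.0
    return calls, fraction
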