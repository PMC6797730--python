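"""Truncation-bias coverage statistic around internal homopolymer runs.

For each transcript carrying an internal A- or T-run, read coverage is
counted at eight fixed positions: 25, 50, 75 and 100 nt upstream and
downstream of the run. The per-transcript maximum of the eight counts
(``max_t``) normalizes the counts to relative coverages, and transcripts
with ``max_t`` above a minimum (default: strictly more than 10 reads)
are averaged position-wise. A 5'-truncation mechanism shows up as
depressed upstream means with downstream means near 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentSet
from .features import HomopolymerRun

__all__ = [
    "DEFAULT_OFFSETS",
    "BiasProfile",
    "positional_coverage",
    "bias_profile",
    "stratified_bias",
    "runny_read_fraction",
]

DEFAULT_OFFSETS = (25, 50, 75, 100)
DEFAULT_MIN_MAX_COV = 10


def _signed_positions(offsets: Sequence[int]) -> tuple[int, ...]:
    offs = sorted(offsets)
    return tuple(-o for o in reversed(offs)) + tuple(offs)


@dataclass(frozen=True)
class BiasProfile:
    """Mean relative coverage (+/- SE) at the signed offset positions.

    ``positions`` are signed offsets relative to the run (negative =
    upstream/5', positive = downstream/3'); ``n_transcripts`` is shared
    by all positions because only runs with full flanks enter.
    """

    positions: tuple[int, ...]
    means: tuple[float, ...]
    stderrs: tuple[float, ...]
    n_transcripts: int
    min_max_cov: int
    comparator: str
    run_base: str
    bin_label: str = "all"

    @property
    def defined(self) -> bool:
        return self.n_transcripts > 0

    def upstream_means(self) -> tuple[float, ...]:
        return tuple(m for p, m in zip(self.positions, self.means) if p < 0)

    def downstream_means(self) -> tuple[float, ...]:
        return tuple(m for p, m in zip(self.positions, self.means) if p > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_label,
                "position": self.positions,
                "mean_relative_coverage": self.means,
                "stderr": self.stderrs,
                "n_transcripts": self.n_transcripts,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin": self.bin_label,
                "run_base": self.run_base,
                "n_transcripts": self.n_transcripts,
                "min_max_cov": self.min_max_cov,
                "comparator": self.comparator,
                "positions": list(self.positions),
                "means": list(self.means),
                "stderrs": list(self.stderrs),
            },
            indent=2,
        )


def positional_coverage(
    aset: AlignmentSet,
    run: HomopolymerRun,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    transcript_length: int | None = None,
) -> dict[int, int]:
    """Read counts at the signed offset positions around one run.

    The upstream position for offset ``o`` is ``run.start - o``; the
    downstream position anchors on the run's last base, ``run.end - 1 +
    o``. A read covers position ``p`` iff ``target_start <= p <
    target_end``. The run must have full flanks (every position on the
    transcript).
    """
    max_off = max(offsets)
    if run.start - max_off < 0:
        raise ValueError(f"run at [{run.start},{run.end}) lacks a {max_off} nt 5' flank")
    if transcript_length is not None and run.end - 1 + max_off >= transcript_length:
        raise ValueError(f"run at [{run.start},{run.end}) lacks a {max_off} nt 3' flank")
    intervals = [
        (aln.target_start, aln.target_end)
        for aln in aset
        if aln.target_id == run.transcript_id
    ]
    return _count_positions(intervals, run, offsets)


def _count_positions(
    intervals: Sequence[tuple[int, int]],
    run: HomopolymerRun,
    offsets: Sequence[int],
) -> dict[int, int]:
    counts: dict[int, int] = {}
    for signed in _signed_positions(offsets):
        if signed < 0:
            pos = run.start + signed
        else:
            pos = run.end - 1 + signed
        counts[signed] = sum(1 for start, end in intervals if start <= pos < end)
    return counts


def bias_profile(
    aset: AlignmentSet,
    runs: Iterable[HomopolymerRun],
    min_max_cov: int = DEFAULT_MIN_MAX_COV,
    comparator: str = "gt",
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    bin_label: str = "all",
) -> BiasProfile:
    """Average relative coverage profile over transcripts.

    ``runs`` holds one analysis run per transcript (see
    :func:`~polytrunc.features.select_analysis_run`). Per transcript the
    eight counts are divided by their maximum ``max_t``; transcripts
    with ``max_t > min_max_cov`` (or ``>=`` with ``comparator='ge'``)
    contribute to the position-wise mean and standard error
    (sd / sqrt(n)). With no kept transcript the profile is returned
    flagged with ``n_transcripts == 0`` and NaN means.
    """
    if comparator not in ("gt", "ge"):
        raise ValueError(f"comparator must be 'gt' or 'ge', got {comparator!r}")
    runs = sorted(runs, key=lambda r: r.transcript_id)
    if len({r.transcript_id for r in runs}) != len(runs):
        raise ValueError("expected at most one analysis run per transcript")
    bases = {r.base for r in runs}
    if len(bases) > 1:
        raise ValueError("profile runs must share one base; analyze A and T separately")
    run_base = bases.pop() if bases else "T"
    grouped = aset.by_target()
    positions = _signed_positions(offsets)
    rows: list[list[float]] = []
    for run in runs:
        intervals = [
            (aln.target_start, aln.target_end)
            for aln in grouped.get(run.transcript_id, ())
        ]
        counts = _count_positions(intervals, run, offsets)
        max_t = max(counts.values())
        keep = max_t > min_max_cov if comparator == "gt" else max_t >= min_max_cov
        if not keep:
            continue
        rows.append([counts[p] / max_t for p in positions])
    n = len(rows)
    if n == 0:
        nan = (math.nan,) * len(positions)
        return BiasProfile(positions, nan, nan, 0, min_max_cov, comparator,
                           run_base, bin_label)
    mat = np.asarray(rows, dtype=float)
    means = mat.mean(axis=0)
    if n > 1:
        stderrs = mat.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        stderrs = np.zeros(len(positions))
    return BiasProfile(
        positions=positions,
        means=tuple(float(m) for m in means),
        stderrs=tuple(float(s) for s in stderrs),
        n_transcripts=n,
        min_max_cov=min_max_cov,
        comparator=comparator,
        run_base=run_base,
        bin_label=bin_label,
    )


def stratified_bias(
    aset: AlignmentSet,
    runs: Iterable[HomopolymerRun],
    bins: Sequence[tuple[int, int | None]] = ((9, 15), (15, None)),
    min_max_cov: int = DEFAULT_MIN_MAX_COV,
    comparator: str = "gt",
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> list[BiasProfile]:
    """One profile per run-length bin (bins half-open, ``None`` = open end)."""
    runs = list(runs)
    profiles: list[BiasProfile] = []
    covered: set[str] = set()
    for lo, hi in bins:
        members = [
            r for r in runs if r.length >= lo and (hi is None or r.length < hi)
        ]
        ids = {r.transcript_id for r in members}
        if ids & covered:
            raise ValueError("run-length bins must be disjoint")
        covered |= ids
        label = f"[{lo},{'inf' if hi is None else hi})"
        profiles.append(
            bias_profile(aset, members, min_max_cov=min_max_cov,
                         comparator=comparator, offsets=offsets, bin_label=label)
        )
    return profiles


def runny_read_fraction(aset: AlignmentSet, runny_ids: Iterable[str]) -> float:
    """Share of retained reads mapping to run-bearing transcripts."""
    runny = set(runny_ids)
    total = len(aset)
    if total == 0:
        raise ValueError("no retained reads")
    return sum(1 for aln in aset if aln.target_id in runny) / total
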