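"""Synthetic long-read generator with the internal-priming truncation mechanism.

The generator emulates a nanopore transcriptome experiment well enough
to exercise every downstream statistic:

* random transcriptomes (~1 kb transcripts) with *planted* internal
  poly(T) or poly(A) runs and no accidental runs elsewhere;
* protocol-specific reads — in cDNA mode, an anchored oligo-dT (TVN)
  primer can anneal to an internal A-run of the first cDNA strand (an
  internal T-run of the mRNA), so the second strand is 5'-truncated at
  the run's 3' boundary; symmetrically, internal poly(T) priming during
  first-strand synthesis 3'-truncates at an A-run. In direct-RNA mode
  reads are 3'-anchored with a configurable chance of a partial 5' start
  (degradation / early pore exit);
* a ~10% sequencing-error model (mismatches plus indels, with extra
  deletions inside homopolymers) applied after truncation, since the
  truncation is a library-preparation artifact, not a sequencing one;
* exact truth alignments for every read, written either as the package's
  truth TSV or as plain SAM with the true CIGAR.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .alignio import AlignmentSet, TranscriptAlignment, TranscriptRecord
from .features import HomopolymerRun, find_homopolymer_runs

__all__ = [
    "SimConfig",
    "SpikeInDesign",
    "SimulatedRead",
    "make_transcriptome",
    "make_spikein_design",
    "simulate_long_reads",
    "simulate_spikein_counts",
    "truth_alignments",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT_U8 = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_U8[_x] = _y

# Step function p(L): probability that an internal run of length L causes
# truncation. The bias is already detectable at 9-mers and pronounced at
# 15-mers, hence the two plateaus.
DEFAULT_TRUNCATION_STEPS: tuple[tuple[int, float], ...] = ((9, 0.3), (15, 0.7))


def step_probability(steps: Sequence[tuple[int, float]], length: int) -> float:
    """Evaluate a (min_run_length, probability) step function at ``length``."""
    prob = 0.0
    for min_len, p in sorted(steps):
        if length >= min_len:
            prob = p
    return prob


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults describe a realistic nanopore run: ~1 kb transcripts, ~10%
    per-base error split between mismatches and indels with a 3x
    deletion surcharge inside homopolymers, and a direct-RNA degradation
    rate chosen so the median single-read horizontal coverage is about
    0.83 (0.5 / degradation_rate when that rate exceeds one half).
    """

    seed: int = 0
    n_transcripts: int = 100
    length_range: tuple[int, int] = (800, 1200)
    runny_fraction: float = 0.3
    planted_run_lengths: tuple[int, ...] = tuple(range(9, 31))
    planted_run_base: str = "T"
    protocol: str = "cdna"  # {"cdna", "rna"}
    truncation_steps: tuple[tuple[int, float], ...] = DEFAULT_TRUNCATION_STEPS
    a_run_truncation_steps: tuple[tuple[int, float], ...] = ()
    degradation_rate: float = 0.6
    mismatch_rate: float = 0.04
    insertion_rate: float = 0.03
    deletion_rate: float = 0.03
    homopolymer_indel_factor: float = 3.0
    depth: float = 30.0
    oversampling_factor: float = 1.0
    min_run_length: int = 9
    flank: int = 100
    lncrna_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.protocol not in ("cdna", "rna"):
            raise ValueError(f"protocol must be 'cdna' or 'rna', got {self.protocol!r}")
        for name in ("runny_fraction", "degradation_rate", "mismatch_rate",
                     "insertion_rate", "deletion_rate", "lncrna_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.oversampling_factor < 1.0:
            raise ValueError("oversampling_factor must be >= 1")
        if self.planted_run_base not in ("A", "T"):
            raise ValueError("planted_run_base must be 'A' or 'T'")


@dataclass(frozen=True)
class SpikeInDesign:
    """Known relative molar concentrations of a synthetic spike-in mix."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("spike-in ids must be unique")
        if any(c <= 0 for c in self.entries.values()):
            raise ValueError("spike-in concentrations must be positive")
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def n(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return sorted(self.entries)


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read plus its ground-truth placement.

    ``target_start``/``target_end`` give the intact (error-free) span of
    the molecule on its transcript; ``cigar`` is the true alignment of
    the error-bearing read sequence to that span, already reversed for
    '-' strand reads whose ``sequence`` is the reverse complement.
    """

    read_id: str
    sequence: str
    quality: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    cigar: str


def _random_clean_sequence(rng: np.random.Generator, length: int,
                           max_run: int, max_tries: int = 200) -> np.ndarray:
    """Random ACGT sequence with no A/T run of length > ``max_run``."""
    for _ in range(max_tries):
        seq = _BASES[rng.integers(0, 4, size=length)]
        if _longest_at_run(seq) <= max_run:
            return seq
    raise RuntimeError("could not draw a run-free background sequence")


def _longest_at_run(seq: np.ndarray) -> int:
    longest = 0
    for target in (ord("A"), ord("T")):
        mask = seq == target
        if not mask.any():
            continue
        # lengths of True runs via cumulative reset
        padded = np.concatenate(([0], mask.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        run_lengths = edges[1::2] - edges[0::2]
        if run_lengths.size:
            longest = max(longest, int(run_lengths.max()))
    return longest


def make_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], list[HomopolymerRun]]:
    """Generate a random transcriptome with planted internal runs.

    Exactly ``round(runny_fraction * n_transcripts)`` transcripts carry
    one planted run of ``planted_run_base``; no other A/T run of
    ``min_run_length`` or more occurs anywhere (rejection-sampled), and
    every planted run keeps at least ``flank`` nt on both sides.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    n_runny = int(round(config.runny_fraction * n))
    runny_idx = set(rng.choice(n, size=n_runny, replace=False).tolist())
    width = max(4, len(str(n)))
    records: list[TranscriptRecord] = []
    planted: list[HomopolymerRun] = []
    run_byte = ord(config.planted_run_base)
    for i in range(n):
        tid = f"TX{i:0{width}d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _random_clean_sequence(rng, length, config.min_run_length - 1)
        if i in runny_idx:
            run_len = int(rng.choice(config.planted_run_lengths))
            if run_len + 2 * config.flank > length:
                raise ValueError(
                    f"planted run of {run_len} nt plus {config.flank} nt flanks "
                    f"does not fit a {length} nt transcript"
                )
            start = int(rng.integers(config.flank, length - config.flank - run_len + 1))
            seq[start : start + run_len] = run_byte
            # keep the planted run maximal: flanking bases must differ
            others = _BASES[_BASES != run_byte]
            for edge in (start - 1, start + run_len):
                if 0 <= edge < length and seq[edge] == run_byte:
                    seq[edge] = rng.choice(others)
            planted.append(
                HomopolymerRun(tid, config.planted_run_base, start, start + run_len)
            )
        biotype = "lncRNA" if rng.random() < config.lncrna_fraction else "protein_coding"
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=f"GENE{i:0{width}d}",
                biotype=biotype,
                sequence=seq.tobytes().decode("ascii"),
            )
        )
    return records, planted


def make_spikein_design(
    n: int = 67, dynamic_range_log10: float = 2.0, seed: int = 0
) -> SpikeInDesign:
    """Log-uniform relative molar concentrations for ``n`` spike-ins."""
    if n < 2:
        raise ValueError("a design needs at least 2 spike-ins")
    if dynamic_range_log10 < 0:
        raise ValueError("dynamic range must be non-negative")
    rng = np.random.default_rng(seed)
    log10_conc = rng.uniform(0.0, dynamic_range_log10, size=n)
    width = len(str(n))
    entries = {
        f"SIRV{i + 1:0{width}d}": float(10.0 ** log10_conc[i]) for i in range(n)
    }
    return SpikeInDesign(entries)


def _homopolymer_mask(seq: np.ndarray, min_len: int = 5) -> np.ndarray:
    """Boolean mask of positions inside any single-base run >= ``min_len``."""
    mask = np.zeros(len(seq), dtype=bool)
    if len(seq) == 0:
        return mask
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(seq)]))
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            mask[s:e] = True
    return mask


def _merge_cigar(ops: list[tuple[str, int]]) -> str:
    merged: list[tuple[str, int]] = []
    for op, length in ops:
        if length == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return "".join(f"{length}{op}" for op, length in merged)


def _apply_errors(
    sub: np.ndarray,
    hp_mask: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """Inject mismatches and indels; return (read bytes, true CIGAR)."""
    n = len(sub)
    if config.mismatch_rate == config.insertion_rate == config.deletion_rate == 0:
        return sub.copy(), f"{n}M"
    p_del = np.where(
        hp_mask,
        min(1.0, config.deletion_rate * config.homopolymer_indel_factor),
        config.deletion_rate,
    )
    del_mask = rng.random(n) < p_del
    ins_mask = rng.random(n) < config.insertion_rate
    mis_mask = (~del_mask) & (rng.random(n) < config.mismatch_rate)
    corrected = sub.copy()
    mis_idx = np.flatnonzero(mis_mask)
    if mis_idx.size:
        shifts = rng.integers(1, 4, size=mis_idx.size)
        corrected[mis_idx] = _BASES[
            (_BASE_INDEX[corrected[mis_idx]] + shifts) % 4
        ]
    ins_bases = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
    parts: list[np.ndarray] = []
    ops: list[tuple[str, int]] = []
    events = np.flatnonzero(del_mask | ins_mask)
    prev = 0
    ins_cursor = 0
    for i in events:
        if i > prev:
            parts.append(corrected[prev:i])
            ops.append(("M", int(i - prev)))
        if ins_mask[i]:
            parts.append(ins_bases[ins_cursor : ins_cursor + 1])
            ins_cursor += 1
            ops.append(("I", 1))
        if del_mask[i]:
            ops.append(("D", 1))
        else:
            parts.append(corrected[i : i + 1])
            ops.append(("M", 1))
        prev = i + 1
    if prev < n:
        parts.append(corrected[prev:n])
        ops.append(("M", int(n - prev)))
    read = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    return read, _merge_cigar(ops)


def _reverse_cigar(cigar: str) -> str:
    ops: list[str] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append(num + ch)
            num = ""
    return "".join(reversed(ops))


def simulate_long_reads(
    transcriptome: Sequence[TranscriptRecord],
    expression: Mapping[str, float],
    config: SimConfig,
) -> list[SimulatedRead]:
    """Simulate one protocol's reads from a transcriptome.

    Per molecule a transcript is drawn proportional to ``expression``;
    the intact span is 3'-anchored and possibly truncated by the
    protocol mechanism; truncated cDNA molecules are replicated
    ``oversampling_factor`` times in expectation (internally-primed
    cDNAs are shorter and amplify better, so they end up over-sampled);
    finally sequencing errors are injected. The error-free span is kept
    as the truth interval.
    """
    if not expression:
        raise ValueError("expression map is empty")
    ids = [rec.transcript_id for rec in transcriptome]
    abundance = np.array([max(0.0, expression.get(t, 0.0)) for t in ids], dtype=float)
    if abundance.sum() <= 0:
        raise ValueError("all expression values are zero")
    probs = abundance / abundance.sum()
    rng = np.random.default_rng([config.seed, 7])

    seqs = [np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8).copy()
            for rec in transcriptome]
    hp_masks = [_homopolymer_mask(s) for s in seqs]
    t_runs = [find_homopolymer_runs(rec, "T", config.min_run_length)
              for rec in transcriptome]
    a_runs = [find_homopolymer_runs(rec, "A", config.min_run_length)
              for rec in transcriptome]

    total = int(round(config.depth * len(transcriptome)))
    draws = rng.choice(len(transcriptome), size=total, p=probs)
    reads: list[SimulatedRead] = []
    serial = 0
    for idx in draws:
        rec = transcriptome[idx]
        length = rec.length
        start, end = 0, length
        truncated = False
        if config.protocol == "rna":
            if config.degradation_rate > 0 and rng.random() < config.degradation_rate:
                start = int(rng.integers(0, length))
        else:  # cdna
            for run in t_runs[idx]:
                p = step_probability(config.truncation_steps, run.length)
                if p > 0 and rng.random() < p:
                    start = max(start, run.end)
                    truncated = True
            for run in a_runs[idx]:
                q = step_probability(config.a_run_truncation_steps, run.length)
                if q > 0 and rng.random() < q:
                    end = min(end, run.start)
                    truncated = True
        if end <= start:
            continue
        n_copies = 1
        if truncated and config.oversampling_factor > 1.0:
            extra = config.oversampling_factor - 1.0
            n_copies = 1 + int(extra) + int(rng.random() < (extra - int(extra)))
        for _ in range(n_copies):
            sub = seqs[idx][start:end]
            read_bytes, cigar = _apply_errors(
                sub, hp_masks[idx][start:end], config, rng
            )
            if len(read_bytes) == 0:
                continue
            if config.protocol == "cdna":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = "+"
            if strand == "-":
                read_bytes = _COMPLEMENT_U8[read_bytes][::-1]
                cigar = _reverse_cigar(cigar)
            read_id = f"read{serial:07d}_{rec.transcript_id}"
            serial += 1
            reads.append(
                SimulatedRead(
                    read_id=read_id,
                    sequence=read_bytes.tobytes().decode("ascii"),
                    quality="I" * len(read_bytes),
                    target_id=rec.transcript_id,
                    target_start=start,
                    target_end=end,
                    strand=strand,
                    cigar=cigar,
                )
            )
    return reads


def truth_alignments(reads: Sequence[SimulatedRead]) -> AlignmentSet:
    """Truth placements of simulated reads as an :class:`AlignmentSet`.

    The truth interval is the intact molecule span; every base of the
    read derives from that span, so the aligned query fraction is 1 and
    truth records always pass the quantification filter.
    """
    alignments = tuple(
        TranscriptAlignment(
            read_id=read.read_id,
            target_id=read.target_id,
            target_start=read.target_start,
            target_end=read.target_end,
            query_length=len(read.sequence),
            query_span=len(read.sequence),
            strand=read.strand,
        )
        for read in reads
    )
    return AlignmentSet(alignments, target_space="transcriptome")


def write_sam(
    reads: Sequence[SimulatedRead],
    transcriptome: Sequence[TranscriptRecord],
    path: str,
) -> None:
    """Write simulated reads as plain SAM with their true CIGAR strings."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": rec.transcript_id, "LN": rec.length} for rec in transcriptome
        ],
    }
    index = {rec.transcript_id: i for i, rec in enumerate(transcriptome)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(read.quality)
            seg.reference_id = index[read.target_id]
            seg.reference_start = read.target_start
            seg.cigarstring = read.cigar
            seg.mapping_quality = 60
            seg.flag = 16 if read.strand == "-" else 0
            out.write(seg)


def simulate_spikein_counts(
    design: SpikeInDesign,
    tech_params: Mapping[str, tuple[float, float, float]],
    seed: int = 0,
) -> dict[str, "QuantTable"]:
    """Simulate per-technology spike-in quantification tables.

    ``tech_params`` maps technology name -> (bias_slope beta, noise_sd
    sigma, library_size). Per technology, the expected signal of
    spike-in *i* is ``concentration_i ** beta * exp(Normal(0, sigma))``,
    scaled so expected counts sum to ``library_size``, then Poisson
    counts are drawn.
    """
    from .quant import QuantTable

    ids = design.ids()
    conc = np.array([design.entries[t] for t in ids], dtype=float)
    out: dict[str, QuantTable] = {}
    for k, name in enumerate(sorted(tech_params)):
        beta, sigma, library_size = tech_params[name]
        if sigma < 0:
            raise ValueError("noise sd must be non-negative")
        rng = np.random.default_rng([seed, 11, k])
        log_mean = beta * np.log(conc)
        if sigma > 0:
            log_mean = log_mean + rng.normal(0.0, sigma, size=len(ids))
        mean = np.exp(log_mean - log_mean.max())
        lam = library_size * mean / mean.sum()
        counts = rng.poisson(lam)
        out[name] = QuantTable(
            level="transcript",
            unit="count",
            values={t: float(c) for t, c in zip(ids, counts)},
        )
    return out
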