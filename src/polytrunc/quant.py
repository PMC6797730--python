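"""Transcript and gene quantification from filtered alignments.

Expression of a transcript is approximated by its number of retained
primary alignments; gene expression is the sum over the gene's
transcripts. On top of the count tables this module provides protocol
comparisons (Spearman on raw values, Pearson on log values), single-read
horizontal-coverage metrics, read-subsampling saturation curves, and the
TE-category quantification-ratio analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignio import AlignmentSet
from .features import TE_CATEGORY_LABELS, te_category

__all__ = [
    "QuantTable",
    "ComparisonResult",
    "CoverageMetrics",
    "count_primary",
    "aggregate_to_genes",
    "compare_quant",
    "single_isoform_coverage_metrics",
    "saturation_curve",
    "te_category_ratio",
    "read_quant_tsv",
    "write_quant_tsv",
]

FULL_LENGTH_THRESHOLD = 0.80


@dataclass(frozen=True)
class QuantTable:
    """id -> non-negative expression value at one level/unit."""

    level: str  # {"transcript", "gene"}
    unit: str  # {"count", "tpm"}
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.unit not in ("count", "tpm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("expression values must be non-negative")
        object.__setattr__(self, "values", dict(self.values))

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    def __len__(self) -> int:
        return len(self.values)

    def get(self, key: str, default: float = 0.0) -> float:
        return self.values.get(key, default)


@dataclass(frozen=True)
class ComparisonResult:
    spearman_rho: float
    pearson_r: float
    n: int
    log_transformed: bool = True
    pseudocount: float = 1.0


@dataclass(frozen=True)
class CoverageMetrics:
    """Per-read horizontal coverage summary over single-isoform transcripts."""

    n_mapped: int
    mean_coverage: float
    median_coverage: float
    full_length_fraction: float
    threshold: float = FULL_LENGTH_THRESHOLD


def count_primary(
    aset: AlignmentSet, transcript_ids: Iterable[str] | None = None
) -> QuantTable:
    """Count retained reads per target transcript.

    ``aset`` must already be filtered (primary, non-supplementary, query
    fraction). Two primary alignments for one read violate the SAM
    contract and raise. With ``transcript_ids`` given, unexpressed
    transcripts are present with count 0.
    """
    counts: dict[str, float] = (
        {t: 0.0 for t in transcript_ids} if transcript_ids is not None else {}
    )
    seen: set[str] = set()
    for aln in aset:
        if not aln.is_primary or aln.is_supplementary:
            raise ValueError("count_primary expects a filtered alignment set")
        if aln.read_id in seen:
            raise ValueError(f"read {aln.read_id!r} has more than one primary alignment")
        seen.add(aln.read_id)
        counts[aln.target_id] = counts.get(aln.target_id, 0.0) + 1.0
    return QuantTable(level="transcript", unit="count", values=counts)


def aggregate_to_genes(q: QuantTable, tmap: Mapping[str, str]) -> QuantTable:
    """Sum transcript values per gene; totals are conserved."""
    if q.level != "transcript":
        raise ValueError("can only aggregate a transcript-level table")
    missing = sorted(t for t in q.values if t not in tmap)
    if missing:
        raise KeyError(f"transcripts without a gene mapping: {missing[:10]}")
    out: dict[str, float] = {}
    for t, v in q.values.items():
        g = tmap[t]
        out[g] = out.get(g, 0.0) + v
    return QuantTable(level="gene", unit=q.unit, values=out)


def compare_quant(
    a: QuantTable,
    b: QuantTable,
    pseudocount: float = 1.0,
    restrict: Iterable[str] | None = None,
    intersect: bool = False,
) -> ComparisonResult:
    """Correlate two quantifications over a shared id universe.

    By default the universe is the union of ids with absentees counted
    as 0 (``intersect=True`` keeps only shared ids). Spearman is
    computed on raw values, Pearson on ``log10(value + pseudocount)``.
    """
    if restrict is not None:
        ids = sorted(set(restrict))
    elif intersect:
        ids = sorted(set(a.values) & set(b.values))
    else:
        ids = sorted(set(a.values) | set(b.values))
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to correlate")
    va = np.array([a.get(t) for t in ids], dtype=float)
    vb = np.array([b.get(t) for t in ids], dtype=float)
    rho = stats.spearmanr(va, vb).statistic
    r = stats.pearsonr(
        np.log10(va + pseudocount), np.log10(vb + pseudocount)
    ).statistic
    return ComparisonResult(
        spearman_rho=float(rho),
        pearson_r=float(r),
        n=len(ids),
        log_transformed=True,
        pseudocount=pseudocount,
    )


def single_isoform_coverage_metrics(
    aset: AlignmentSet,
    single_isoform_ids: Iterable[str],
    transcript_lengths: Mapping[str, int],
    threshold: float = FULL_LENGTH_THRESHOLD,
) -> CoverageMetrics:
    """Horizontal coverage of single-isoform transcripts by individual reads.

    Per read, coverage = (target_end - target_start) / transcript
    length; the summary gives the mean, the median, and the
    "full-length" fraction of reads covering more than ``threshold`` of
    their transcript. All mapped reads on the listed transcripts are
    used (no query-fraction filter).
    """
    wanted = set(single_isoform_ids)
    coverages = [
        (aln.target_end - aln.target_start) / transcript_lengths[aln.target_id]
        for aln in aset
        if aln.target_id in wanted
    ]
    if not coverages:
        raise ValueError("no reads on the listed transcripts")
    arr = np.asarray(coverages, dtype=float)
    return CoverageMetrics(
        n_mapped=len(arr),
        mean_coverage=float(arr.mean()),
        median_coverage=float(np.median(arr)),
        full_length_fraction=float((arr > threshold).mean()),
        threshold=threshold,
    )


def saturation_curve(
    assignments: Sequence[str],
    depths: Sequence[int],
    n_reps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Distinct transcripts detected vs subsampled read depth.

    ``assignments`` lists the assigned transcript of each read (primary
    alignment for long reads, best alignment for short reads; any
    biotype restriction is applied by the caller). Per depth, reads are
    subsampled uniformly without replacement ``n_reps`` times and the
    number of transcripts with at least one sampled read is averaged.
    """
    labels = np.asarray(assignments)
    total = len(labels)
    if total == 0:
        raise ValueError("no read assignments")
    for d in depths:
        if not 1 <= d <= total:
            raise ValueError(f"depth {d} outside [1, {total}]")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        distinct = [
            len(np.unique(labels[rng.choice(total, size=d, replace=False)]))
            for _ in range(n_reps)
        ]
        arr = np.asarray(distinct, dtype=float)
        rows.append(
            {
                "depth": d,
                "mean_distinct": float(arr.mean()),
                "sd_distinct": float(arr.std(ddof=1)) if n_reps > 1 else 0.0,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def te_category_ratio(
    qa: QuantTable,
    qb: QuantTable,
    te_fraction: Mapping[str, float],
    labels: Sequence[str] = TE_CATEGORY_LABELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of log2(qa/qb) per exonic-TE-coverage category.

    Only genes expressed in both tables (value > 0) enter. Returns a
    per-gene frame (gene, te_fraction, category, log2_ratio) and a
    per-category summary with n and quartiles; empty categories appear
    with n = 0.
    """
    genes = sorted(
        g for g in set(qa.values) & set(qb.values)
        if qa.get(g) > 0 and qb.get(g) > 0
    )
    missing = [g for g in genes if g not in te_fraction]
    if missing:
        raise KeyError(f"genes without a TE fraction: {missing[:10]}")
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "te_fraction": [te_fraction[g] for g in genes],
            "category": [te_category(te_fraction[g]) for g in genes],
            "log2_ratio": [math.log2(qa.get(g) / qb.get(g)) for g in genes],
        }
    )
    rows = []
    for label in labels:
        vals = per_gene.loc[per_gene["category"] == label, "log2_ratio"]
        if len(vals):
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25 = q50 = q75 = math.nan
        rows.append(
            {"category": label, "n": len(vals), "q25": q25, "median": q50, "q75": q75}
        )
    return per_gene, pd.DataFrame(rows)


def read_quant_tsv(path: str, level: str = "transcript", unit: str = "count") -> QuantTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"quant TSV {path!r} needs id and value columns")
    id_col, val_col = df.columns[0], df.columns[1]
    return QuantTable(
        level=level,
        unit=unit,
        values={str(r[id_col]): float(r[val_col]) for _, r in df.iterrows()},
    )


def write_quant_tsv(q: QuantTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{q.level}_id\t{q.unit}\n")
        for key in sorted(q.values):
            value = q.values[key]
            out = int(value) if float(value).is_integer() else value
            fh.write(f"{key}\t{out}\n")
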