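import numpy as np
import pytest

from polytrunc.alignio import AlignmentSet, TranscriptAlignment, TranscriptRecord
from polytrunc.simulate import SimConfig, make_transcriptome, simulate_long_reads, truth_alignments


def make_aln(read_id, target_id, start, end, query_length=None, query_span=None,
             secondary=False, supplementary=False, strand="+"):
    """Shorthand constructor: full-span perfect alignment unless overridden."""
    span = end - start
    if query_length is None:
        query_length = span
    if query_span is None:
        query_span = min(span, query_length)
    return TranscriptAlignment(
        read_id=read_id,
        target_id=target_id,
        target_start=start,
        target_end=end,
        query_length=query_length,
        query_span=query_span,
        is_secondary=secondary,
        is_supplementary=supplementary,
        strand=strand,
    )


@pytest.fixture(scope="session")
def small_transcriptome():
    """50 transcripts, 15 with planted T-runs, error-free friendly config."""
    config = SimConfig(seed=11, n_transcripts=50, runny_fraction=0.3, depth=25,
                       mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
                       degradation_rate=0.0)
    records, planted = make_transcriptome(config)
    return config, records, planted


@pytest.fixture(scope="session")
def errorfree_cdna_reads(small_transcriptome):
    config, records, planted = small_transcriptome
    expression = {rec.transcript_id: 1.0 for rec in records}
    reads = simulate_long_reads(records, expression, config)
    return records, planted, reads, truth_alignments(reads)
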