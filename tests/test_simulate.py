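"""Generator determinism, the truncation mechanism, and the error model."""

import numpy as np
import pytest

from polytrunc.alignio import filter_alignments, write_fasta
from polytrunc.features import find_homopolymer_runs
from polytrunc.simulate import (
    SimConfig,
    SpikeInDesign,
    make_spikein_design,
    make_transcriptome,
    simulate_long_reads,
    simulate_spikein_counts,
    step_probability,
    truth_alignments,
)


def _expression(records):
    return {rec.transcript_id: 1.0 for rec in records}


class TestMakeTranscriptome:
    def test_exact_runny_count(self):
        config = SimConfig(seed=2, n_transcripts=100, runny_fraction=0.3)
        _, planted = make_transcriptome(config)
        assert len(planted) == 30

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        config = SimConfig(seed=7, n_transcripts=40)
        paths = []
        for name in ("a.fasta", "b.fasta"):
            records, _ = make_transcriptome(config)
            path = tmp_path / name
            write_fasta(records, str(path))
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_planted_runs_redetected_exactly(self):
        config = SimConfig(seed=3, n_transcripts=60, runny_fraction=0.5)
        records, planted = make_transcriptome(config)
        by_id = {rec.transcript_id: rec for rec in records}
        detected = {}
        for rec in records:
            runs = find_homopolymer_runs(rec, config.planted_run_base,
                                         config.min_run_length)
            if runs:
                detected[rec.transcript_id] = [(r.start, r.end) for r in runs]
        expected = {p.transcript_id: [(p.start, p.end)] for p in planted}
        assert detected == expected
        # planted runs keep full flanks
        for p in planted:
            assert p.start >= config.flank
            assert p.end <= by_id[p.transcript_id].length - config.flank

    def test_no_accidental_runs_on_clean_transcripts(self):
        config = SimConfig(seed=4, n_transcripts=50, runny_fraction=0.0)
        records, planted = make_transcriptome(config)
        assert planted == []
        for rec in records:
            for base in "AT":
                assert find_homopolymer_runs(rec, base, config.min_run_length) == []

    def test_infeasible_geometry_errors(self):
        config = SimConfig(seed=0, n_transcripts=5, runny_fraction=1.0,
                           length_range=(150, 160), planted_run_lengths=(20,))
        with pytest.raises(ValueError):
            make_transcriptome(config)


class TestTruncationMechanism:
    def test_p_one_clips_every_runny_read(self):
        config = SimConfig(seed=5, n_transcripts=30, runny_fraction=0.4, depth=20,
                           truncation_steps=((9, 1.0),), degradation_rate=0.0,
                           mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0)
        records, planted = make_transcriptome(config)
        run_end = {p.transcript_id: p.end for p in planted}
        reads = simulate_long_reads(records, _expression(records), config)
        assert any(r.target_id in run_end for r in reads)
        for read in reads:
            if read.target_id in run_end:
                assert read.target_start >= run_end[read.target_id]

    def test_p_zero_full_spans(self):
        config = SimConfig(seed=6, n_transcripts=20, runny_fraction=0.4, depth=10,
                           truncation_steps=(), degradation_rate=0.0,
                           mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0)
        records, _ = make_transcriptome(config)
        lengths = {rec.transcript_id: rec.length for rec in records}
        reads = simulate_long_reads(records, _expression(records), config)
        for read in reads:
            assert (read.target_start, read.target_end) == (0, lengths[read.target_id])

    def test_planted_probability_recovered(self):
        p = 0.6
        config = SimConfig(seed=8, n_transcripts=40, runny_fraction=0.5, depth=60,
                           planted_run_lengths=(15,), truncation_steps=((9, p),),
                           degradation_rate=0.0, mismatch_rate=0.0,
                           insertion_rate=0.0, deletion_rate=0.0)
        records, planted = make_transcriptome(config)
        run_end = {r.transcript_id: r.end for r in planted}
        reads = simulate_long_reads(records, _expression(records), config)
        runny_reads = [r for r in reads if r.target_id in run_end]
        clipped = sum(r.target_start == run_end[r.target_id] for r in runny_reads)
        frac = clipped / len(runny_reads)
        sd = np.sqrt(p * (1 - p) / len(runny_reads))
        assert abs(frac - p) < 4 * sd

    def test_oversampling_inflates_runny_share(self):
        base = dict(seed=9, n_transcripts=40, runny_fraction=0.25, depth=40,
                    truncation_steps=((9, 1.0),), degradation_rate=0.0,
                    mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0)
        records, planted = make_transcriptome(SimConfig(**base))
        runny_ids = {p.transcript_id for p in planted}
        reads = simulate_long_reads(records, _expression(records),
                                    SimConfig(**base, oversampling_factor=2.0))
        share = sum(r.target_id in runny_ids for r in reads) / len(reads)
        assert share > 0.25

    def test_rna_mode_three_prime_anchored(self):
        config = SimConfig(seed=10, n_transcripts=20, runny_fraction=0.3, depth=15,
                           protocol="rna", degradation_rate=0.8,
                           mismatch_rate=0.0, insertion_rate=0.0, deletion_rate=0.0)
        records, _ = make_transcriptome(config)
        lengths = {rec.transcript_id: rec.length for rec in records}
        reads = simulate_long_reads(records, _expression(records), config)
        assert all(r.target_end == lengths[r.target_id] for r in reads)
        assert any(r.target_start > 0 for r in reads)
        assert all(r.strand == "+" for r in reads)


class TestErrorModelAndTruth:
    def test_realized_error_rate_near_ten_percent(self):
        """Edits counted against the truth over >=1e5 bases are ~10% with defaults."""
        import re

        from polytrunc.features import reverse_complement

        config = SimConfig(seed=12, n_transcripts=30, runny_fraction=0.0, depth=5,
                           mismatch_rate=0.04, insertion_rate=0.03,
                           deletion_rate=0.03, homopolymer_indel_factor=1.0,
                           degradation_rate=0.0)
        records, _ = make_transcriptome(config)
        seqs = {rec.transcript_id: rec.sequence for rec in records}
        reads = simulate_long_reads(records, _expression(records), config)
        edits = bases = 0
        for read in reads:
            true_sub = seqs[read.target_id][read.target_start:read.target_end]
            query = read.sequence
            cigar = read.cigar
            if read.strand == "-":
                query = reverse_complement(query)
                ops = re.findall(r"\d+[MID]", cigar)
                cigar = "".join(reversed(ops))
            # independent per-base walk over the true alignment
            qpos = rpos = 0
            for num, op in re.findall(r"(\d+)([MID])", cigar):
                num = int(num)
                if op == "M":
                    edits += sum(
                        query[qpos + k] != true_sub[rpos + k] for k in range(num)
                    )
                    qpos += num
                    rpos += num
                elif op == "I":
                    edits += num
                    qpos += num
                else:
                    edits += num
                    rpos += num
            assert rpos == len(true_sub) and qpos == len(query)
            bases += len(true_sub)
        assert bases > 1e5
        assert abs(edits / bases - 0.10) < 0.005

    def test_truth_passes_filter_with_fraction_one(self):
        config = SimConfig(seed=13, n_transcripts=15, runny_fraction=0.3, depth=10)
        records, _ = make_transcriptome(config)
        truth = truth_alignments(
            simulate_long_reads(records, _expression(records), config)
        )
        assert all(a.aligned_query_fraction == 1.0 for a in truth)
        assert len(filter_alignments(truth)) == len(truth)

    def test_determinism_same_seed(self):
        config = SimConfig(seed=14, n_transcripts=15, runny_fraction=0.3, depth=10)
        records, _ = make_transcriptome(config)
        r1 = simulate_long_reads(records, _expression(records), config)
        r2 = simulate_long_reads(records, _expression(records), config)
        assert r1 == r2

    def test_empty_expression_errors(self):
        config = SimConfig(seed=1, n_transcripts=5)
        records, _ = make_transcriptome(config)
        with pytest.raises(ValueError):
            simulate_long_reads(records, {}, config)
        with pytest.raises(ValueError):
            simulate_long_reads(
                records, {r.transcript_id: 0.0 for r in records}, config
            )


class TestSpikeIns:
    def test_design_size_and_determinism(self):
        d1 = make_spikein_design(seed=1)
        d2 = make_spikein_design(seed=1)
        assert d1.n == 67
        assert d1.entries == d2.entries

    def test_zero_dynamic_range_equal_concentrations(self):
        design = make_spikein_design(n=10, dynamic_range_log10=0.0, seed=2)
        assert set(design.entries.values()) == {1.0}

    def test_invalid_design_args(self):
        with pytest.raises(ValueError):
            make_spikein_design(n=1)
        with pytest.raises(ValueError):
            make_spikein_design(dynamic_range_log10=-1.0)
        with pytest.raises(ValueError):
            SpikeInDesign({"a": 0.0})

    def test_noiseless_counts_rank_perfectly(self):
        from scipy.stats import spearmanr

        # well-separated concentrations so Poisson noise cannot swap ranks
        design = make_spikein_design(n=10, dynamic_range_log10=3.0, seed=3)
        tables = simulate_spikein_counts(
            design, {"tech": (1.0, 0.0, 1e8)}, seed=3
        )
        ids = design.ids()
        rho = spearmanr(
            [tables["tech"].get(t) for t in ids],
            [design.entries[t] for t in ids],
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_loglog_regression_recovers_slope(self):
        design = make_spikein_design(seed=4)
        tables = simulate_spikein_counts(design, {"tech": (1.0, 0.0, 1e7)}, seed=4)
        ids = design.ids()
        x = np.log([design.entries[t] for t in ids])
        y = np.log([tables["tech"].get(t) + 1.0 for t in ids])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_counts_deterministic(self):
        design = make_spikein_design(seed=5)
        params = {"a": (1.0, 0.3, 1e6), "b": (0.8, 0.5, 1e6)}
        t1 = simulate_spikein_counts(design, params, seed=6)
        t2 = simulate_spikein_counts(design, params, seed=6)
        assert {k: v.values for k, v in t1.items()} == {k: v.values for k, v in t2.items()}


def test_step_probability():
    steps = ((9, 0.3), (15, 0.7))
    assert step_probability(steps, 8) == 0.0
    assert step_probability(steps, 9) == 0.3
    assert step_probability(steps, 14) == 0.3
    assert step_probability(steps, 15) == 0.7
    assert step_probability(steps, 30) == 0.7
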