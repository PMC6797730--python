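# Methods

## The truncation-bias statistic

For a transcript carrying an internal homopolymer run of T's (or A's),
read coverage is counted at eight fixed positions: 25, 50, 75 and
100 nt upstream and downstream of the run. Upstream positions anchor on
the run's first base (`run.start − offset`), downstream positions on
its last base (`run.end − 1 + offset`), so the offsets are symmetric
about the run body; a read covers a position `p` when its alignment
interval satisfies `target_start ≤ p < target_end` (all coordinates
0-based half-open). The per-transcript normalizer `max_t` is the
maximum of the eight counts; relative coverage is count / `max_t`, and
the profile is the position-wise mean over all transcripts with
`max_t > 10` (strictly greater by default; a `comparator="ge"` flag
switches to ≥), with standard errors sd/√n.

A 5′-truncation mechanism acting at T-runs depresses the four upstream
means while leaving the downstream means at ≈1; 3′-truncation at A-runs
mirrors this. Under the generative model below, the expected upstream
mean is simply the survival probability 1 − p of the truncation event.

One run per transcript enters the statistic. Only runs with at least
`flank` (default 100) nt on both sides qualify, so that all eight
positions exist on the transcript and every kept transcript contributes
to all eight positions (constant n across positions). Among qualifying
runs the longest is chosen, ties broken 5′-most. Transcripts whose runs
all fail the flank rule are excluded. A- and T-run analyses are run
independently; reads are never deduplicated — every retained primary
alignment counts.

Run-length stratification partitions transcripts by the length of
their analysis run into disjoint half-open bins (default [9,15) and
[15,∞)) and computes one profile per bin; a single covering bin
reproduces the unstratified profile exactly.

## Alignment filtering and quantification

The quantification path keeps primary, non-supplementary alignments
whose *aligned query fraction* is at least 0.80. The fraction is the
number of query bases in M/=/X/I CIGAR operations divided by the full
read length including soft- and hard-clipped bases, i.e. the share of
the molecule the alignment explains. Reads aligned on *less* than 80%
of their length are removed, so the boundary value 0.80 is retained.
Insertions count as aligned; clips do not; reference-only operations
(D/N) affect neither numerator nor denominator, so spliced genome
alignments are treated consistently.

Transcript expression is the number of retained reads per target; a
second primary alignment for the same read violates the SAM contract
and is an error. Gene expression is the sum over the gene's
transcripts (totals conserved). Protocol agreement is summarized by
Spearman's ρ on raw values and Pearson's r on log10(value + 1); the id
universe defaults to the union of both tables with absentees as zero
(an `intersect` flag restricts to shared ids), since dropping ids
silently would hide protocol-specific losses.

Horizontal-coverage metrics (mean, median, and the "full-length"
fraction of reads covering > 0.80 of their transcript) are computed
over *all* mapped reads on single-isoform transcripts, without the 80%
query filter — the filter would condition on the very quantity being
measured. The saturation curve subsamples read→transcript assignments
uniformly without replacement at each depth (default 30 replicates) and
counts distinct transcripts hit; its expectation has the closed form
Σ_t (1 − C(N−n_t, d)/C(N, d)), which the tests use as an oracle.

## Spike-in model comparison

Against a design of known relative molar concentrations, each
technology's quantification is evaluated (a) by correlation and (b) as
a predictor in the log-linear model

    log(concentration) = μ + β · log(predictor + pseudocount) + ε

fitted by OLS in natural log. Cross-validation draws, per repeat, a
fresh uniformly random partition into ⌊0.8 n⌋ training and the
remaining test spike-ins (67 → 53/14), reusing the same partition for
every predictor within a repeat so MSE differences reflect predictors,
not folds; 30 repeats by default. Reported per predictor: the
per-repeat test MSEs, their [min, max] spread, and mean ± 1.96·SE.
Pseudocounts default to 1 on counts/TPMs and 0 on concentrations
(which must be positive). Ids can be excluded (e.g. a known outlier
spike-in); exclusions apply to every train and test set.

Per-spike-in residuals from full-data fits support a reproducibility
check: the Spearman correlation of residual vectors across replicate
pairs of one technology (high when errors are a stable
technology-specific bias, ≈0 for pure noise), and the worst-predicted
spike-in (largest mean squared residual) per technology.

## The synthetic generator

The generator emulates a nanopore transcriptome experiment:

- **Transcriptome**: `n_transcripts` random sequences (default
  800–1200 nt, matching ~1 kb reads), rejection-sampled so no
  accidental A/T run of ≥9 nt exists; an exact `round(runny_fraction·n)`
  subset receives one planted run (base T by default, lengths drawn
  from 9–30) with ≥100 nt flanks and non-extendable boundaries.
  Biotypes are protein_coding with a 20% lncRNA admixture.
- **Truncation** (cDNA mode): each T-run of length L independently
  truncates the molecule 5′ to the run's 3′ boundary with probability
  p(L); A-runs symmetrically truncate 3′ with q(L). p(L) is a step
  function, default 0.3 for L ≥ 9 rising to 0.7 for L ≥ 15 — the bias
  is detectable at 9-mers and pronounced at 15-mers; no quantitative
  curve is established, so the shape is exposed in the config.
  Truncated molecules can be over-replicated by a configurable factor
  (default 1, i.e. off) to mimic the shorter-fragment amplification
  advantage.
- **Degradation** (direct-RNA mode): reads are 3′-anchored; with
  probability `degradation_rate` the 5′ start is uniform along the
  transcript (degradation / early pore exit). With rate r > ½ the
  median horizontal coverage is 0.5/r and the mean 1 − r/2; the default
  r = 0.6 gives median ≈0.83 and mean 0.70, typical of published
  direct-RNA runs.
- **Errors**: applied after truncation (the truncation is a
  library-preparation artifact, not a sequencing one). Per base:
  mismatch 0.04, insertion 0.03, deletion 0.03, with the deletion rate
  multiplied by 3 inside any homopolymer of ≥5 nt — together ≈10%
  edits, reproducing the coverage dip direct-RNA reads show at
  homopolymers. cDNA reads take either strand; direct-RNA reads are
  strand-specific.
- **Truth**: every read records its intact (error-free) span and the
  true CIGAR of the errored sequence. Truth can be written as a plain
  TSV or as SAM; for error-free reads both routes yield bit-identical
  downstream statistics (a tested invariant). Truth records have
  aligned query fraction 1 by construction and always pass the filter.
- **Spike-ins**: designs default to 67 entries log-uniform over 2
  decades (a realistic mix dynamic range). Technology count tables use
  log-mean β·log(conc) plus Normal(0, σ) noise, scaled to a library
  size, with Poisson sampling.

Everything is a pure function of the config and seed; identical
configs give byte-identical FASTA/FASTQ/TSV/SAM outputs.

What the generator does *not* emulate: basecalling signal, realistic
quality strings (flat Q40), PCR chimeras, multi-isoform genes, biased
fragment start positions beyond the uniform model, or alignment
ambiguity (truth placements are exact). Passing tests therefore
demonstrate the statistics recover a planted mechanism under clean
mapping, not robustness to aligner artifacts on real data.

## Splice sites and TE categories

Intron donor/acceptor dinucleotides are read on the annotated strand
(first and last two intronic bases); canonical means GT..AG. For
unstranded cDNA-derived alignments `accept_reverse` also accepts
CT..AC on the forward strand (the same intron read from the other
strand); for strand-specific direct-RNA alignments it should stay off.
Introns shorter than 4 nt are counted non-canonical. Fractions are per
intron occurrence, not per distinct intron.

Exonic TE coverage of a gene is |union(exons) ∩ union(repeats)| /
|union(exons)| (union semantics, so interval overlap and order are
immaterial). Genes are binned into four categories — 0% (no exonic
TE), (0,1/3], (1/3,2/3], (2/3,1] — and the long/short-read
quantification ratio is summarized per category as log2 ratios with
quartiles, over genes expressed in both tables.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; SAM's 1-based POS is
  converted on ingest.
- The truth TSV stores the integer `query_span` rather than the float
  fraction so records round-trip exactly.
- Empty bias profiles (no transcript passing `max_t`) are returned
  flagged with n = 0 and NaN means rather than raising, so stratified
  bins may be empty.
- Degenerate OLS inputs (all predictor values equal after log) raise;
  a test fold smaller than 2 raises.
- Problem sizes in the test suite and acceptance script (hundreds of
  transcripts, depth 25–50, 10⁴-sequence oracle sweeps) were chosen as
  the smallest sizes at which sampling error is clearly below the
  effects being measured.
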