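# Methods

## Scope and data model

`ampvar` implements the downstream stages of an ensemble amplicon variant
pipeline: it starts from per-combination VCF callsets and per-aligner
alignments and ends at a ranked report. Alignment, variant calling, local
realignment and annotation-database lookups are upstream of the package;
their products are inputs. Gene/annotation columns come from an optional
user-supplied TSV joined on the variant key.

Variant identity is the normalized `(chrom, pos, ref, alt)` tuple: shared
trailing bases are trimmed, then shared leading bases (keeping one anchor
base for indels), and — when a reference context is available — pure
insertions/deletions are shifted to their leftmost equivalent placement.
Left alignment is this package's choice for reconciling the callers'
differing indel representations; merging is exact-key, with no fuzzy or
windowed matching, so it is deterministic and auditable. Multi-allelic VCF
records are split into one call per alternate allele before normalization,
which makes per-combination support counting well defined. VCF positions
are 1-based, BED intervals 0-based half-open; conversion happens only at
I/O boundaries (pysam does the parsing and writing). Missing quality
annotations are represented as absent, never as sentinel values, because
the filter semantics distinguish absent from zero.

## Filtering stages

**Region filter.** A call survives iff its normalized anchor position lies
inside some BED interval. Membership is tested on the anchor base only, not
the full deletion span — the simplest rule consistent with dropping
off-target calls; amplicon panels rarely truncate a variant at the panel
edge.

**Quality expressions.** GATK-caller callsets: SNPs/MNPs are labeled by
`DP < 5`, `QUAL < 50.0`, `QD < 0.7`, `FS > 60.0` (for bwa-aligned callsets
the FS cut-off is 590.0 — strand-bias scores distribute very differently
under that aligner on amplicon data), `MQ0 >= 4 && MQ0/(1.0*DP) > 0.1`,
and membership in a cluster of ≥ 3 SNPs spanning ≤ 10 bp. The cluster-size
companion to the 10 bp window is not independently specified anywhere, so
the upstream tool's default of 3 is adopted (configurable). Indels are
labeled by `QD < 2.5 || ReadPosRankSum < -20.0 || FS > 200.0`. In both
expressions a missing field makes its sub-expression match
(missing-evaluates-as-failing), labeled `MISSING_<FIELD>`; this
deliberately also labels calls lacking ReadPosRankSum. SAMtools-caller
callsets get the depth-range filter `2 ≤ DP ≤ 4000` (gap-adjacency windows
default to 0, i.e. disabled). **Union retention**: within each caller
group, a key is retained if at least one aligner combination left it
unlabeled; the rule is stated for the GATK group and applied symmetrically
to the SAMtools group as the least-surprising extension. A retained key
survives in every combination of the group that called it, which is what
makes the full confidence range reachable.

**Homopolymer indel filter.** For each candidate indel (an indel key that
survived the first two stages) and each aligner's reads, the reads covering
the anchor position and exhibiting an I/D CIGAR event matched to the site
contribute their signed event length (+len insertion, −len deletion). Two
statistics summarize the resulting multiset:

* `var` — population variance (divide by *n*) of the lengths, in bp². The
  divide-by-*n* convention is the plainer reading of "variance of the
  length" and keeps `var = 0` for a single event; it is configurable in
  the sense that the statistic is computed from the raw lengths and a
  caller can substitute its own estimator.
* `frmode` — count of the modal length divided by the number of
  *event-bearing* reads (covering reads without an event are excluded from
  the denominator). Tied modes share the same count, so the statistic is
  well defined under ties.

Signed lengths are pooled in one distribution: an insertion/deletion
mixture at one site then registers as maximal dispersion, which is exactly
the error signature the filter targets. Event-to-site matching defaults to
`exact`: the event's anchor base (the reference position of the last
aligned base before the I/D, the same anchor a normalized VCF key uses)
must equal the site's normalized position. A `homopolymer_run` mode is
provided (requires the reference) that accepts any event anchored inside
the homopolymer run containing the site, including the anchor base
immediately left of it, because event placement inside a run is
aligner-dependent; exact mode needs no reference and is the default.

Thresholds: a candidate is rejected iff for at least one aligner
`var > maxVar` **and** `frmode < minFrmode`, both strict — a site sitting
exactly on a threshold is retained, mirroring how the thresholds are
constructed (below). The any-aligner rule is deliberately conservative:
one aligner revealing dispersion is enough to distrust the candidate.
Aligners with no indel-bearing reads at the site contribute no statistics
and are skipped rather than treated as violations; a site where no aligner
has events is retained for lack of evidence.

**Calibration.** Given a labeled training table, `maxVar` is the maximum
`var` and `minFrmode` the minimum `frmode` over the TP entries. Combined
with the strict rejection inequality this guarantees zero TP rejection on
the training set (property-tested over random training sets). FP entries
never enter the formula; they only measure the achieved filtering. The
shipped defaults `maxVar = 0.055`, `minFrmode = 0.9790` are the operating
point of that construction on a Sanger-validated cohort of 108 homopolymer
indel calls (18 TP, 90 FP).

## Merging, score and report

Merging produces one record per distinct key with the exact set of
supporting combinations; the confidence score is the size of that set and
is always computed, never stored. The score is computed over *post-filter*
callsets — a call filtered out of a combination does not count — following
the pipeline order (filtering precedes merging). Conflicting annotation
values across combinations are aggregated as max QUAL and median DP for
the report's representative columns; the per-combination DPs are also kept
as separate columns. Report rows are ordered by descending confidence,
ties in genomic order. Coverage tables count a read toward an amplicon on
any ≥ 1-base overlap of its aligned reference span (so a read may count
toward overlapping amplicons).

Sensitivity and specificity are TP/(TP+FN) and TN/(TN+FP), reported as
percentages rounded half-away-from-zero to two decimals; a zero
denominator yields "undefined", never 0 or 100. Variants with known
alternate-allele fraction below 10% are excluded from benchmark evaluation
(validation chemistry cannot resolve them) but stay in the report.

## Synthetic data

The generators emulate the statistical structure the filters assume, not
the sequencing chemistry:

* **Pileups** place reads (default length 100 bp, mirroring typical
  amplicon read lengths) across a ~400 bp snippet with a planted 8 bp
  homopolymer run. Each read covering the candidate site shows the true
  event; with probability `slippage_prob` its length is perturbed by ±1 bp
  (the dominant flow-sequencer error mode; a perturbation reaching zero
  flips to the opposite-sign 1 bp event so perturbed reads remain
  indel-bearing; magnitude-2 slips can be had by composing perturbations).
  With slippage off, `var = 0` and `frmode = 1` by construction.
* **Callsets** include each true variant in each combination independently
  with probability `1 − dropout`, with healthy annotations drawn from
  ranges well inside the filter thresholds (DP 100–1000, QUAL 100–2000,
  QD 5–20, FS 0–30, MQ0 = 0), so merged confidence is Binomial(6, 1−p)
  conditioned on ≥ 1 call.
* **Training sets** default to 18 TP / 90 FP entries, the shape of the
  real training cohort; TPs use per-entry slippage drawn from [0, 0.05],
  FPs from [0.6, 0.9]. These are this package's defaults for what a
  clearly separated true/artifact population looks like at 40× local
  depth.
* The toy run directory plants SNPs at slots spaced wider than the
  SNP-cluster window so that the noise-free dataset is lossless through
  the quality filters by design.

What the synthetic data does **not** model: base-call qualities and
substitution errors, strand structure (FS values are drawn, not derived),
mapping ambiguity across aligners (the three "aligners" differ only by
random seed), real homopolymer length-dependence of slippage rates, and
allele fractions. Passing tests therefore demonstrate the correctness of
the filtering/merging logic and its guarantees, not the field accuracy of
the thresholds on real flow-sequencer data — the shipped default
thresholds carry that empirical content. In particular, near-total FP
removal on the synthetic training cohort reflects its clean separation;
on real data the same construction removes a substantially smaller
fraction.

## Numerical and degenerate-input choices

Percent rounding is half-away-from-zero on the percent scale (matches the
two-decimal conventions of the benchmark figures). Variant keys sort by
(chrom as string, pos, ref, alt); all outputs are written in that order,
making every stage byte-reproducible. Empty inputs follow the contracts:
empty region list removes everything; empty training TP set, empty
per-aligner statistics list and zero-weight score distributions raise
errors rather than guessing. The pipeline validates configuration (declared
combinations, file existence) before any stage runs and writes a manifest
accounting for every input variant as retained or rejected with a reason.
Problem sizes in the test-suite simulations (≤ 1000 variants, ≤ 200 reads
per pileup, 108-entry training tables) were chosen as the smallest sizes at
which the binomial/statistical assertions have comfortable 3σ margins.

## Known limitations

* No CRAM input, contig liftover or strand flipping; inputs are assumed
  reference-stranded, as amplicon panels and VCF are.
* The homopolymer filter consumes candidate indels from upstream callers;
  it does not discover candidates by scanning runs.
* Quality annotations (QD, FS, MQ0, ReadPosRankSum) are consumed, never
  recomputed from reads.
* Exact-mode event matching can miss events that an aligner placed at a
  different position within a run; `homopolymer_run` mode addresses this
  at the cost of requiring the reference.
* The confidence score treats all six combinations as exchangeable; no
  weighting by aligner/caller quality is attempted.
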