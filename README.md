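# ampvar

Filtering, ensemble merging and reporting of amplicon-sequencing variant
calls — the downstream half of a targeted clinical resequencing workflow.
`ampvar` consumes the outputs a practitioner already has (per-aligner
SAM/BAM files, per-caller VCFs, the amplicon BED panel) and turns them into
a ranked, filtered variant report. It is aimed at users of benchtop
amplicon panels (e.g. cancer hotspot panels sequenced on flow-based
instruments such as Ion Torrent PGM), where homopolymer slippage makes
indel calls unreliable and no single aligner/caller pair can be trusted
alone.

## What it does

Variants called by every combination of aligners (default: bwa, bowtie2,
NextGenMap) and callers (default: GATK, SAMtools) pass through three
filtering stages and a merge:

1. **Region filter** — calls outside the BED amplicon panel are dropped.
2. **Quality expression filters** — GATK-caller callsets get the classic
   expression set for SNPs (`DP < 5`, `QUAL < 50`, `QD < 0.7`, `FS > 60`
   — `FS > 590` for bwa — `MQ0 >= 4 && MQ0/DP > 0.1`, 3-SNP clusters
   within 10 bp) and indels (`QD < 2.5 || ReadPosRankSum < -20 ||
   FS > 200`), with missing fields evaluating as failing; SAMtools-caller
   callsets get a depth-range filter (2 ≤ DP ≤ 4000). Within each caller
   group a variant survives if **at least one** aligner combination left it
   unlabeled (union retention).
3. **Homopolymer indel filter** — for every candidate indel and every
   aligner's reads, two statistics are computed over the reads covering the
   site that show an indel there: *var*, the population variance of the
   signed event lengths (+insertion/−deletion, in bp), and *frmode*, the
   fraction of those reads carrying the modal length. A candidate is
   rejected iff for **some** aligner

   ```
   var > maxVar   and   frmode < minFrmode
   ```

   (both strict). The default thresholds (maxVar = 0.055,
   minFrmode = 0.9790) are the extremes of *var* and *frmode* over a
   Sanger-confirmed true-positive training cohort, and `ampvar calibrate`
   re-derives them from any labeled training table the same way — so no
   training TP is ever rejected, by construction.
4. **Merge + confidence score** — surviving callsets are merged on the
   normalized `(chrom, pos, ref, alt)` key; each variant's confidence
   score is the number of supporting combinations (1–6 by default). The
   report ranks variants by descending score; sensitivity is TP/(TP+FN)
   and specificity TN/(TN+FP), reported as two-decimal percentages.

Seeded synthetic generators (`ampvar.simulate`) produce pileups with
tunable homopolymer slippage, callsets with tunable dropout, labeled
training tables and complete toy run directories, so the whole pipeline is
testable without any external data.

## Worked example

```bash
ampvar simulate --seed 11 -d data/
ampvar run run.yaml           # config pointing at data/, see examples/
```

or, from Python (`examples/05_full_pipeline.py`):

```text
simulated 5 true variants (SNPs + one homopolymer deletion)

final report (ranked by confidence):
chrom  pos ref alt type  confidence
 chr1   61   T   C  SNP           6
 chr1   74   G   A  SNP           6
 chr1  113   A   G  SNP           6
 chr1  152   G   A  SNP           6
 chr1  200  GT   G  DEL           6
```

With dropout and slippage off, every simulated variant survives all three
filter stages and is found by all six aligner × caller combinations —
confidence 6, the maximum under the default grid. The benchmark arithmetic
example (`examples/04_benchmark_metrics.py`) prints:

```text
sensitivity = TP/(TP+FN) = 92.01%
specificity = TN/(TN+FP) = 99.98%
overlap with integrated calls: 92.56%
mean confidence, variants confirmed by the truth set: 5.79
mean confidence, variants found in addition:          2.41
```

— high-scoring variants are overwhelmingly the externally confirmed ones,
which is why the score works as a prioritization criterion.

The other examples cover variant normalization and the quality expressions
(`01`), the homopolymer filter and its calibration (`02`), and merging with
dropout (`03`). The CLI exposes each stage as a subcommand
(`filter-region`, `filter-quality`, `calibrate`, `filter-indels`, `merge`,
`report`, `metrics`, `simulate`, `run`).

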