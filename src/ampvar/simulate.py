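"""Deterministic synthetic fixtures for every pipeline stage.

The generators emulate the statistical structure the filters assume:

* pileups over a reference snippet containing homopolymer runs, with a
  tunable "slippage" probability that a read's indel event length is
  perturbed by +-1 bp — the dominant flow-sequencing error mode in
  homopolymer runs;
* per-combination callsets with tunable dropout, so merged confidence
  scores have a known binomial distribution;
* labeled training-indel tables mixing low-dispersion (TP-like) and
  high-dispersion (FP-like) pileups.

All randomness is confined to a seed in the config; identical seeds give
identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .homopolymer import compute_frmode, compute_var, extract_event_lengths
from .model import (
    AlignedRead,
    CallSet,
    ComboId,
    GenomicInterval,
    QualityAnnotations,
    TrainingIndel,
    VariantCall,
    VariantKey,
    default_combos,
)

_BASES = "ACGT"


def make_reference(
    length: int = 400,
    runs: Sequence[tuple[int, str, int]] = ((200, "T", 8),),
    seed: int = 0,
) -> str:
    """Random reference snippet with homopolymer runs planted at given offsets.

    ``runs`` lists (0-based offset, base, run length); outside the runs the
    sequence avoids accidental runs longer than 2.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_BASES), size=length))
    for i in range(2, length):
        while seq[i] == seq[i - 1] == seq[i - 2]:
            seq[i] = rng.choice(list(_BASES))
    for offset, base, run_len in runs:
        seq[offset : offset + run_len] = [base] * run_len
        # break up accidental extensions of the planted run
        if offset > 0 and seq[offset - 1] == base:
            seq[offset - 1] = _BASES[(_BASES.index(base) + 1) % 4]
        end = offset + run_len
        if end < length and seq[end] == base:
            seq[end] = _BASES[(_BASES.index(base) + 1) % 4]
    return "".join(seq)


@dataclass(frozen=True)
class PileupSimConfig:
    """Reads piled over one candidate indel site.

    ``true_length`` is the signed event length every read would show without
    noise (+insertion / -deletion); ``None`` simulates an error-only site
    where a read shows a spurious +-1 event with probability
    ``slippage_prob``. With a true event, slippage perturbs the length by
    +-1; a perturbation that would reach 0 flips to the opposite-sign 1 bp
    event so every perturbed read still bears an indel.
    """

    reference: str
    site_pos: int  # 1-based anchor position of the candidate
    true_length: Optional[int] = -1
    n_reads: int = 30
    slippage_prob: float = 0.0
    read_length: int = 100
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.slippage_prob <= 1.0):
            raise ValueError("slippage_prob must be in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.true_length == 0:
            raise ValueError("true_length must be non-zero (or None)")
        if not (1 <= self.site_pos <= len(self.reference)):
            raise ValueError("indel site outside reference snippet")


def _read_with_event(
    rid: str,
    chrom: str,
    start: int,
    read_length: int,
    site_pos: int,
    event_length: Optional[int],
    ref_end: int,
) -> AlignedRead:
    """One read of query length ``read_length`` anchored to show the event.

    CIGAR is left-M, the I/D event anchored at ``site_pos``, right-M; the
    right M is clipped so the alignment stays inside the reference.
    """
    left = site_pos - start + 1
    if event_length is None:
        span = min(read_length, ref_end - start + 1)
        return AlignedRead(rid, chrom, start, (("M", span),))
    if event_length > 0:  # insertion consumes query only
        right = read_length - left - event_length
    else:  # deletion consumes reference only
        right = read_length - left
    right = min(right, ref_end - (site_pos - event_length if event_length < 0 else site_pos))
    if right < 1:
        right = 1
    cigar: list[tuple[str, int]] = [("M", left)]
    if event_length > 0:
        cigar.append(("I", event_length))
    else:
        cigar.append(("D", -event_length))
    cigar.append(("M", right))
    return AlignedRead(rid, chrom, start, tuple(cigar))


def _perturb(length: int, rng: np.random.Generator) -> int:
    new = length + (1 if rng.random() < 0.5 else -1)
    if new == 0:
        new = -1 if length > 0 else 1
    return new


def simulate_pileup(cfg: PileupSimConfig) -> list[AlignedRead]:
    """Generate reads covering the site per the pileup config (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    ref_end = len(cfg.reference)
    lo = max(1, cfg.site_pos - cfg.read_length + 10)
    hi = max(lo, cfg.site_pos - 5)
    reads = []
    for i in range(cfg.n_reads):
        start = int(rng.integers(lo, hi + 1))
        if cfg.true_length is not None:
            length: Optional[int] = cfg.true_length
            if rng.random() < cfg.slippage_prob:
                length = _perturb(cfg.true_length, rng)
        else:
            if rng.random() < cfg.slippage_prob:
                length = 1 if rng.random() < 0.5 else -1
            else:
                length = None
        reads.append(
            _read_with_event(
                f"read{i:04d}", cfg.chrom, start, cfg.read_length,
                cfg.site_pos, length, ref_end,
            )
        )
    return reads


@dataclass(frozen=True)
class CallsetSimConfig:
    """Per-combination callsets over a shared list of true variants."""

    true_variants: tuple[VariantKey, ...]
    combos: tuple[ComboId, ...] = tuple(default_combos())
    dropout_prob: float = 0.0
    dp_range: tuple[int, int] = (100, 1000)
    qual_range: tuple[float, float] = (100.0, 2000.0)
    qd_range: tuple[float, float] = (5.0, 20.0)
    fs_range: tuple[float, float] = (0.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if not self.combos:
            raise ValueError("combo list must be non-empty")


def simulate_callsets(cfg: CallsetSimConfig) -> list[CallSet]:
    """Each true variant enters each combo's callset with prob 1 - dropout."""
    rng = np.random.default_rng(cfg.seed)
    callsets = []
    for combo in cfg.combos:
        calls = []
        for key in cfg.true_variants:
            if rng.random() < cfg.dropout_prob:
                continue
            ann = QualityAnnotations(
                qual=float(rng.uniform(*cfg.qual_range)),
                dp=int(rng.integers(cfg.dp_range[0], cfg.dp_range[1] + 1)),
                qd=float(rng.uniform(*cfg.qd_range)),
                fs=float(rng.uniform(*cfg.fs_range)),
                mq0=0,
                read_pos_rank_sum=float(rng.uniform(-2.0, 2.0)),
            )
            calls.append(VariantCall(key, ann, combo))
        callsets.append(CallSet(combo, calls))
    return callsets


def simulate_training_set(
    n_tp: int = 18,
    n_fp: int = 90,
    tp_noise: float = 0.05,
    fp_noise: float = 0.6,
    seed: int = 0,
    n_reads: int = 40,
) -> list[TrainingIndel]:
    """Labeled training indels with TP-like and FP-like dispersion.

    Each entry is a real simulated pileup at a homopolymer deletion site:
    TP entries use a per-entry slippage drawn uniformly from [0, tp_noise],
    FP entries from [fp_noise, min(1, fp_noise + 0.3)]. var/frmode are
    computed from the pileup with the same extraction code the filter uses.
    The default 18 TP / 90 FP shape mirrors a Sanger-validated training
    cohort of 108 homopolymer indel calls.
    """
    if n_tp < 1:
        raise ValueError("need at least one TP entry")
    rng = np.random.default_rng(seed)
    reference = make_reference(seed=seed)
    site_pos = 200  # anchor just left of the planted homopolymer run
    entries = []
    specs = [("TP", float(rng.uniform(0.0, tp_noise))) for _ in range(n_tp)]
    specs += [
        ("FP", float(rng.uniform(fp_noise, min(1.0, fp_noise + 0.3))))
        for _ in range(n_fp)
    ]
    run_base = reference[site_pos]  # first base of the run (0-based index = pos)
    for i, (label, slip) in enumerate(specs):
        pile_seed = int(rng.integers(0, 2**31 - 1))
        pile = simulate_pileup(
            PileupSimConfig(
                reference=reference,
                site_pos=site_pos,
                true_length=-1,
                n_reads=n_reads,
                slippage_prob=slip,
                seed=pile_seed,
            )
        )
        site = VariantKey("chr1", site_pos, reference[site_pos - 1] + run_base, reference[site_pos - 1])
        dist = extract_event_lengths(pile, site, mode="exact")
        entries.append(
            TrainingIndel(
                site=VariantKey(f"train{i}", site_pos, site.ref, site.alt),
                label=label,
                var=compute_var(dist),
                frmode=compute_frmode(dist),
            )
        )
    return entries


@dataclass(frozen=True)
class RunSimConfig:
    """A complete toy run directory: reference, reads, callsets, regions."""

    n_snps: int = 4
    with_true_indel: bool = True
    aligners: tuple[str, ...] = ("bwa", "bowtie2", "nextgenmap")
    callers: tuple[str, ...] = ("gatk", "samtools")
    dropout_prob: float = 0.0
    slippage_prob: float = 0.0
    n_reads_per_aligner: int = 40
    seed: int = 0


def simulate_run_dir(outdir: str | os.PathLike, cfg: RunSimConfig) -> dict[str, object]:
    """Write a self-contained toy dataset in standard formats.

    Emits reference FASTA, BED target regions, one SAM per aligner, one VCF
    per combination, a training TSV and a truth table. Returns a manifest of
    the paths and true variant keys.
    """
    from . import formats  # deferred: keeps simulate importable without pysam at doc time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    reference = make_reference(length=400, runs=((200, "T", 8),), seed=cfg.seed)
    chrom = "chr1"
    regions = [GenomicInterval(chrom, 50, 350, "AMP1")]

    # true variants: SNPs spread over the amplicon, plus one homopolymer deletion
    # slots spaced wider than the SNP-cluster window so the noise-free toy
    # dataset never triggers cluster flagging by accident
    slots = np.arange(61, 190, 13)
    snp_positions = sorted(
        int(p) for p in rng.choice(slots, size=cfg.n_snps, replace=False)
    )
    truth: list[VariantKey] = []
    for pos in snp_positions:
        ref_base = reference[pos - 1]
        alt = _BASES[(_BASES.index(ref_base) + 2) % 4]
        truth.append(VariantKey(chrom, pos, ref_base, alt))
    indel_anchor = 200  # anchor base immediately left of the T-run
    if cfg.with_true_indel:
        truth.append(
            VariantKey(chrom, indel_anchor, reference[indel_anchor - 1] + "T", reference[indel_anchor - 1])
        )

    combos = tuple(ComboId(a, c) for a in cfg.aligners for c in cfg.callers)
    callsets = simulate_callsets(
        CallsetSimConfig(
            true_variants=tuple(truth),
            combos=combos,
            dropout_prob=cfg.dropout_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )

    manifest: dict[str, object] = {"reference": str(outdir / "reference.fa")}
    formats.write_reference({chrom: reference}, outdir / "reference.fa")
    formats.write_regions(regions, outdir / "regions.bed")
    manifest["regions"] = str(outdir / "regions.bed")

    sam_paths = {}
    for aligner in cfg.aligners:
        pile = simulate_pileup(
            PileupSimConfig(
                reference=reference,
                site_pos=indel_anchor,
                true_length=-1 if cfg.with_true_indel else None,
                n_reads=cfg.n_reads_per_aligner,
                slippage_prob=cfg.slippage_prob,
                chrom=chrom,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        # background coverage across the amplicon for the coverage table
        for i in range(10):
            start = 51 + i * 25
            span = min(100, len(reference) - start + 1)
            pile.append(AlignedRead(f"bg{i:03d}", chrom, start, (("M", span),)))
        path = outdir / f"reads_{aligner}.sam"
        formats.write_alignments(pile, path, {chrom: len(reference)})
        sam_paths[aligner] = str(path)
    manifest["alignments"] = sam_paths

    vcf_paths = {}
    for cs in callsets:
        path = outdir / f"calls_{cs.combo.label}.vcf"
        formats.write_callset(cs, path)
        vcf_paths[cs.combo.label] = str(path)
    manifest["callsets"] = vcf_paths

    training = simulate_training_set(seed=int(rng.integers(0, 2**31 - 1)))
    formats.write_training_table(training, outdir / "training.tsv")
    manifest["training"] = str(outdir / "training.tsv")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(truth):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\n")
    manifest["truth"] = str(outdir / "truth.tsv")
    manifest["true_variants"] = sorted(truth)
    return manifest
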