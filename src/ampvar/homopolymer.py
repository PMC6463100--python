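"""Homopolymer indel error filter.

Flow-based sequencers (Ion Torrent) mis-call the length of homopolymer runs,
producing spurious indel candidates. True indels are supported consistently:
nearly every indel-bearing read at the site shows the same event length.
Error-driven candidates show a spread of lengths instead. Two per-site,
per-aligner statistics capture this:

* ``var`` — population variance (bp^2) of the signed indel event lengths
  (insertions positive, deletions negative) across the reads covering the
  site that show an indel there;
* ``frmode`` — the fraction of those indel-bearing reads carrying the modal
  event length.

Thresholds (maxVar, minFrmode) are calibrated from a labeled training set:
maxVar is the largest ``var`` seen among true-positive training indels and
minFrmode the smallest ``frmode``, so by construction no true positive is
rejected. A candidate is rejected when, for at least one aligner,
``var > maxVar`` and ``frmode < minFrmode`` (both strict) — the conservative
any-aligner rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .filters import FilterVerdict
from .model import (
    AlignedRead,
    ContractError,
    HomopolymerThresholds,
    NoEventsError,
    TrainingIndel,
    VariantKey,
)
from .variants import ReferenceContext, require_indel_like


@dataclass
class IndelLengthDistribution:
    """Signed indel event lengths observed at one site in one aligner's reads."""

    site: VariantKey
    aligner: str
    lengths: list[int] = field(default_factory=list)
    n_covering: int = 0

    def __post_init__(self) -> None:
        if any(l == 0 for l in self.lengths):
            raise ValueError("event lengths must be non-zero")
        if len(self.lengths) > self.n_covering:
            raise ValueError("more events than covering reads")


def homopolymer_run(reference: ReferenceContext, pos: int) -> tuple[int, int]:
    """1-based inclusive bounds of the homopolymer run containing ``pos``."""
    base = reference.base(pos)
    if base is None:
        raise ValueError(f"position {pos} outside reference context")
    start = pos
    while reference.base(start - 1) == base:
        start -= 1
    end = pos
    while reference.base(end + 1) == base:
        end += 1
    return start, end


def extract_event_lengths(
    reads: Sequence[AlignedRead],
    site: VariantKey,
    reference: Optional[ReferenceContext] = None,
    mode: Literal["exact", "homopolymer_run"] = "exact",
) -> IndelLengthDistribution:
    """Collect signed indel event lengths at ``site`` from a set of reads.

    A read covers the site when its aligned reference span includes the
    site's anchor position. In ``exact`` mode an I/D event counts when its
    anchor coordinate equals the site's normalized position; in
    ``homopolymer_run`` mode (requires ``reference``) any event anchored
    inside the homopolymer run containing the site counts — the run of the
    first varied base, extended one base left to include events anchored on
    the base preceding the run. Covering reads without a matching event
    increment ``n_covering`` only.
    """
    require_indel_like(site)
    if mode == "homopolymer_run":
        if reference is None:
            raise ValueError("homopolymer_run mode requires a reference context")
        run_start, run_end = homopolymer_run(reference, site.pos + 1)
        lo, hi = run_start - 1, run_end
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    dist = IndelLengthDistribution(site=site, aligner="", lengths=[], n_covering=0)
    for read in reads:
        if read.chrom != site.chrom:
            continue
        start, end = read.reference_span
        if not (start <= site.pos <= end):
            continue
        dist.n_covering += 1
        for anchor, length in read.indel_events():
            if mode == "exact":
                matched = anchor == site.pos
            else:
                matched = lo <= anchor <= hi
            if matched:
                dist.lengths.append(length)
                break  # one event per read per site
    return dist


def compute_var(d: IndelLengthDistribution) -> float:
    """Population variance (divide by n) of the signed event lengths, in bp^2."""
    if not d.lengths:
        raise NoEventsError(f"no indel events at {d.site}")
    return float(np.var(np.asarray(d.lengths, dtype=float)))


def compute_frmode(d: IndelLengthDistribution) -> float:
    """Fraction of indel-bearing reads carrying the modal event length.

    The denominator counts only reads showing an indel at the site, not all
    covering reads. Under mode ties any tied mode gives the same fraction.
    """
    if not d.lengths:
        raise NoEventsError(f"no indel events at {d.site}")
    counts = Counter(d.lengths)
    return max(counts.values()) / len(d.lengths)


def calibrate(training: Sequence[TrainingIndel]) -> HomopolymerThresholds:
    """Derive (maxVar, minFrmode) from the TP-labeled training indels.

    maxVar is the maximum ``var`` and minFrmode the minimum ``frmode``
    observed among TPs, so the strict rejection rule can never reject a
    training TP. FP entries do not enter the formula; they only measure the
    filtering achieved.
    """
    tps = [t for t in training if t.label == "TP"]
    if not tps:
        raise ValueError("calibration requires at least one TP-labeled training indel")
    return HomopolymerThresholds(
        max_var=max(t.var for t in tps),
        min_frmode=min(t.frmode for t in tps),
    )


def decide(
    stats: Sequence[tuple[float, float]],
    thresholds: HomopolymerThresholds,
) -> FilterVerdict:
    """Accept or reject one candidate site given per-aligner (var, frmode) pairs.

    Rejected (HP_INDEL) iff some aligner has var > max_var AND
    frmode < min_frmode — both strict, both from the same aligner. Aligners
    with no events are expected to have been skipped by the caller.
    """
    if not stats:
        raise ContractError("decide requires statistics from at least one aligner")
    for var, frmode in stats:
        if var > thresholds.max_var and frmode < thresholds.min_frmode:
            return FilterVerdict.fail("HP_INDEL")
    return FilterVerdict.ok()


def site_statistics(
    site: VariantKey,
    reads_by_aligner: dict[str, Sequence[AlignedRead]],
    reference: Optional[ReferenceContext] = None,
    mode: Literal["exact", "homopolymer_run"] = "exact",
) -> dict[str, tuple[float, float]]:
    """Per-aligner (var, frmode) at a site; aligners with no events are skipped."""
    stats: dict[str, tuple[float, float]] = {}
    for aligner, reads in reads_by_aligner.items():
        dist = extract_event_lengths(reads, site, reference=reference, mode=mode)
        dist.aligner = aligner
        if dist.lengths:
            stats[aligner] = (compute_var(dist), compute_frmode(dist))
    return stats


def filter_homopolymer_indels(
    sites: Sequence[VariantKey],
    reads_by_aligner: dict[str, Sequence[AlignedRead]],
    thresholds: HomopolymerThresholds,
    reference: Optional[ReferenceContext] = None,
    mode: Literal["exact", "homopolymer_run"] = "exact",
) -> dict[VariantKey, FilterVerdict]:
    """Run the homopolymer filter over candidate indel sites.

    Sites where no aligner shows any indel event are retained (the filter has
    no evidence to reject on).
    """
    verdicts: dict[VariantKey, FilterVerdict] = {}
    for site in sites:
        stats = site_statistics(site, reads_by_aligner, reference=reference, mode=mode)
        if not stats:
            verdicts[site] = FilterVerdict.ok()
        else:
            verdicts[site] = decide(list(stats.values()), thresholds)
    return verdicts
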