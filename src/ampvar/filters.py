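"""Region and quality-expression filters.

The first two filtering stages: (1) drop calls outside the amplicon target
regions; (2) label calls failing caller-specific quality expressions — a
GATK-style SNP expression set (with an aligner-specific Fisher-strand
override for bwa and SNP-cluster flagging), a GATK-style indel expression,
and a SAMtools-style depth-range filter — then retain, per caller group,
every key that passed in at least one combination (union retention).

Missing-value semantics follow the upstream tools' missing-fails switch: a
sub-expression whose annotation field is absent counts as matched, labeling
the call with MISSING_<FIELD>.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .model import CallSet, ContractError, GenomicInterval, VariantCall, VariantKey
from .variants import classify_variant, require_indel_like, require_snp_like, VariantType


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of a filter evaluation; ``passed`` iff no rule fired."""

    reasons: frozenset[str] = frozenset()

    @property
    def passed(self) -> bool:
        return not self.reasons

    @staticmethod
    def ok() -> "FilterVerdict":
        return FilterVerdict()

    @staticmethod
    def fail(*reasons: str) -> "FilterVerdict":
        return FilterVerdict(frozenset(reasons))


@dataclass(frozen=True)
class SnpFilterConfig:
    """GATK-style SNP filter expression thresholds.

    A SNP is labeled when DP < min_dp, QUAL < min_qual, QD < min_qd,
    FS > max_fs (590 instead of 60 for bwa-aligned callsets), or
    MQ0 >= mq0_count together with MQ0/DP > mq0_ratio. Clusters of
    >= cluster_size SNPs spanning <= cluster_window bp are labeled too.
    """

    min_dp: int = 5
    min_qual: float = 50.0
    min_qd: float = 0.7
    max_fs: float = 60.0
    max_fs_bwa: float = 590.0
    mq0_count: int = 4
    mq0_ratio: float = 0.1
    cluster_window: int = 10
    cluster_size: int = 3

    def __post_init__(self) -> None:
        if self.cluster_window < 0:
            raise ValueError("cluster_window must be >= 0")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")

    def fs_threshold(self, aligner: str) -> float:
        return self.max_fs_bwa if aligner == "bwa" else self.max_fs


@dataclass(frozen=True)
class IndelFilterConfig:
    """GATK-style indel filter: QD < min_qd || ReadPosRankSum < min || FS > max."""

    min_qd: float = 2.5
    min_read_pos_rank_sum: float = -20.0
    max_fs: float = 200.0


@dataclass(frozen=True)
class DepthFilterConfig:
    """SAMtools-style depth-range filter (vcfutils varFilter semantics)."""

    min_cov: int = 2
    max_cov: int = 4000
    gap_window: int = 0
    adjacent_gap_window: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_cov <= self.max_cov):
            raise ValueError("require 0 <= min_cov <= max_cov")


def build_region_index(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end, region)
    return trees


def region_filter(
    calls: Sequence[VariantCall], regions: Sequence[GenomicInterval]
) -> list[VariantCall]:
    """Retain calls whose normalized anchor position lies in a target region.

    Membership is tested on the anchor base only (pos - 1 in 0-based
    coordinates), against 0-based half-open intervals. Order preserved.
    """
    index = build_region_index(regions)
    retained = []
    for call in calls:
        tree = index.get(call.key.chrom)
        if tree is not None and tree.overlaps_point(call.key.pos - 1):
            retained.append(call)
    return retained


def evaluate_snp_filters(call: VariantCall, cfg: SnpFilterConfig) -> FilterVerdict:
    """Apply the SNP quality expressions to one SNP/MNP call.

    Every sub-expression that matches contributes a reason; absent fields
    make their sub-expression match, contributing MISSING_<FIELD>.
    """
    require_snp_like(call.key)
    ann = call.annotations
    reasons: set[str] = set()

    if ann.dp is None:
        reasons.add("MISSING_DP")
    elif ann.dp < cfg.min_dp:
        reasons.add("LOW_DP")

    if ann.qual is None:
        reasons.add("MISSING_QUAL")
    elif ann.qual < cfg.min_qual:
        reasons.add("LOW_QUAL")

    if ann.qd is None:
        reasons.add("MISSING_QD")
    elif ann.qd < cfg.min_qd:
        reasons.add("LOW_QD")

    if ann.fs is None:
        reasons.add("MISSING_FS")
    elif ann.fs > cfg.fs_threshold(call.combo.aligner):
        reasons.add("HIGH_FS")

    # MQ0 >= count && MQ0/DP > ratio; a missing field in the conjunction
    # makes the whole expression match
    if ann.mq0 is None:
        reasons.add("MISSING_MQ0")
    elif ann.mq0 >= cfg.mq0_count:
        if ann.dp is None:
            reasons.add("MISSING_DP")
        elif ann.dp > 0 and ann.mq0 / (1.0 * ann.dp) > cfg.mq0_ratio:
            reasons.add("MQ0_RATIO")

    return FilterVerdict(frozenset(reasons))


def flag_snp_clusters(
    calls: Sequence[VariantCall], cfg: SnpFilterConfig
) -> dict[VariantKey, FilterVerdict]:
    """Flag SNPs in clusters of >= cluster_size spanning <= cluster_window bp.

    Calls must come from one callset sorted by (chrom, pos). Non-SNP calls
    pass through unflagged.
    """
    verdicts: dict[VariantKey, FilterVerdict] = {
        c.key: FilterVerdict.ok() for c in calls
    }
    snps = [c for c in calls if classify_variant(c.key) == VariantType.SNP]
    for _, group in groupby(snps, key=lambda c: c.key.chrom):
        chrom_calls = list(group)
        positions = [c.key.pos for c in chrom_calls]
        k = cfg.cluster_size
        for i in range(len(positions) - k + 1):
            if positions[i + k - 1] - positions[i] <= cfg.cluster_window:
                for call in chrom_calls[i : i + k]:
                    verdicts[call.key] = FilterVerdict.fail("SNP_CLUSTER")
    return verdicts


def evaluate_indel_filters(call: VariantCall, cfg: IndelFilterConfig) -> FilterVerdict:
    """Apply the indel quality expression (a disjunction) to one indel call."""
    require_indel_like(call.key)
    ann = call.annotations
    reasons: set[str] = set()

    if ann.qd is None:
        reasons.add("MISSING_QD")
    elif ann.qd < cfg.min_qd:
        reasons.add("INDEL_EXPR")

    if ann.read_pos_rank_sum is None:
        reasons.add("MISSING_READPOSRANKSUM")
    elif ann.read_pos_rank_sum < cfg.min_read_pos_rank_sum:
        reasons.add("INDEL_EXPR")

    if ann.fs is None:
        reasons.add("MISSING_FS")
    elif ann.fs > cfg.max_fs:
        reasons.add("INDEL_EXPR")

    return FilterVerdict(frozenset(reasons))


def depth_filter(call: VariantCall, cfg: DepthFilterConfig) -> FilterVerdict:
    """Depth-range filter for SAMtools-caller callsets: min_cov <= DP <= max_cov."""
    dp = call.annotations.dp
    if dp is None:
        return FilterVerdict.fail("MISSING_DP")
    if dp < cfg.min_cov or dp > cfg.max_cov:
        return FilterVerdict.fail("DEPTH_RANGE")
    return FilterVerdict.ok()


def label_callset(
    callset: CallSet,
    snp_cfg: SnpFilterConfig | None = None,
    indel_cfg: IndelFilterConfig | None = None,
    depth_cfg: DepthFilterConfig | None = None,
) -> CallSet:
    """Apply the quality expressions appropriate to the callset's caller.

    GATK-caller callsets get the SNP expression set (including cluster
    flagging) and the indel expression; SAMtools-caller callsets get the
    depth-range filter. Labels accumulate in each call's ``filter_labels``.
    """
    snp_cfg = snp_cfg or SnpFilterConfig()
    indel_cfg = indel_cfg or IndelFilterConfig()
    depth_cfg = depth_cfg or DepthFilterConfig()

    ordered = sorted(callset.calls, key=lambda c: (c.key.chrom, c.key.pos))
    labeled: list[VariantCall] = []
    if callset.combo.caller == "samtools":
        for call in callset.calls:
            verdict = depth_filter(call, depth_cfg)
            labeled.append(call.with_labels(call.filter_labels | verdict.reasons))
    else:
        cluster = flag_snp_clusters(ordered, snp_cfg)
        for call in callset.calls:
            kind = classify_variant(call.key)
            if kind in (VariantType.SNP, VariantType.MNP):
                verdict = evaluate_snp_filters(call, snp_cfg)
                reasons = verdict.reasons | cluster[call.key].reasons
            else:
                reasons = evaluate_indel_filters(call, indel_cfg).reasons
            labeled.append(call.with_labels(call.filter_labels | reasons))
    return CallSet(callset.combo, labeled)


def retain_union(callsets: Sequence[CallSet]) -> set[VariantKey]:
    """Keys passing (unlabeled) in at least one callset of a caller group."""
    retained: set[VariantKey] = set()
    for cs in callsets:
        for call in cs.calls:
            if not call.filter_labels:
                retained.add(call.key)
    return retained


def apply_union_retention(callsets: Sequence[CallSet]) -> list[CallSet]:
    """Per caller group, keep each combo's calls whose key passed somewhere.

    A key labeled in every combination of its caller group is dropped from
    all of them; a key that passed in at least one survives in every combo
    that called it (its labels are cleared — the group vouched for it).
    """
    combos = [cs.combo for cs in callsets]
    if len(set(combos)) != len(combos):
        raise ContractError("duplicate ComboId across callsets")
    by_caller: dict[str, list[CallSet]] = {}
    for cs in callsets:
        by_caller.setdefault(cs.combo.caller, []).append(cs)

    surviving: list[CallSet] = []
    for cs in callsets:
        retained = retain_union(by_caller[cs.combo.caller])
        kept = [c.with_labels(frozenset()) for c in cs.calls if c.key in retained]
        surviving.append(CallSet(cs.combo, kept))
    return surviving
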