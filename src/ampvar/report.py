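"""Reporting and benchmark metrics.

Per-amplicon coverage tables, the ranked final report (variants ordered by
descending confidence score), summary distributions (per gene, per score,
per variant type) and the confusion-matrix benchmark metrics
(sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import pandas as pd

from .filters import build_region_index
from .merge import MergedVariant
from .model import AlignedRead, GenomicInterval, VariantKey
from .variants import classify_variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def round_pct(value: float, ndigits: int = 2) -> float:
    """Round-half-away-from-zero on the percent scale."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_metrics(c: ConfusionCounts) -> tuple[Optional[float], Optional[float]]:
    """(sensitivity %, specificity %), two decimals; None when undefined.

    A zero denominator (no condition positives / negatives) yields None for
    the affected metric rather than a conventional 0 or 100.
    """
    sensitivity = (
        round_pct(100.0 * c.tp / (c.tp + c.fn)) if (c.tp + c.fn) > 0 else None
    )
    specificity = (
        round_pct(100.0 * c.tn / (c.tn + c.fp)) if (c.tn + c.fp) > 0 else None
    )
    return sensitivity, specificity


def mean_confidence(dist: Mapping[int, float]) -> float:
    """Weighted mean score of a score -> percentage distribution, two decimals."""
    total = sum(dist.values())
    if not dist or total <= 0:
        raise ValueError("distribution must have positive total weight")
    return round_pct(sum(score * pct for score, pct in dist.items()) / total)


def overlap_fraction(n_overlap: int, n_truth: int) -> float:
    """Percentage of a truth set recovered, two decimals."""
    if n_truth <= 0:
        raise ValueError("truth set must be non-empty")
    return round_pct(100.0 * n_overlap / n_truth)


def benchmark_confusion(
    called: set[VariantKey],
    truth: set[VariantKey],
    n_positions: int,
    alt_fraction: Optional[Mapping[VariantKey, float]] = None,
    maf_threshold: float = 0.1,
) -> ConfusionCounts:
    """Confusion counts of a callset against a truth set over ``n_positions``.

    True negatives are positions carrying neither a call nor a truth variant.
    Calls whose alternate-allele fraction is known and below ``maf_threshold``
    are excluded from the evaluation (they stay in the report; orthogonal
    validation chemistry cannot resolve them), as are truth entries below it.
    """
    if alt_fraction:
        called = {
            k
            for k in called
            if alt_fraction.get(k) is None or alt_fraction[k] >= maf_threshold
        }
        truth = {
            k
            for k in truth
            if alt_fraction.get(k) is None or alt_fraction[k] >= maf_threshold
        }
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = n_positions - len(called | truth)
    if tn < 0:
        raise ValueError("n_positions smaller than the union of calls and truth")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def amplicon_coverage(
    reads_by_aligner: Mapping[str, Sequence[AlignedRead]],
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Reads mapped per amplicon per aligner (rows = amplicons, cols = aligners).

    A read counts toward an amplicon when its aligned reference span overlaps
    the interval by at least one base; reads spanning several overlapping
    amplicons count toward each.
    """
    index = build_region_index(regions)
    labels = [r.name if r.name else f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    counts = {aligner: dict.fromkeys(labels, 0) for aligner in reads_by_aligner}
    region_label = dict(zip(regions, labels))
    for aligner, reads in reads_by_aligner.items():
        for read in reads:
            tree = index.get(read.chrom)
            if tree is None:
                continue
            start, end = read.reference_span  # 1-based inclusive
            for hit in tree.overlap(start - 1, end):
                counts[aligner][region_label[hit.data]] += 1
    table = pd.DataFrame(counts, index=labels, columns=sorted(reads_by_aligner))
    table.index.name = "amplicon"
    return table


def build_report(
    merged: Sequence[MergedVariant],
    annotations: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Assemble the ranked final report plus its summary distributions.

    Rows are ordered by descending confidence, ties in genomic order. The
    optional ``annotations`` table (columns chrom, pos, ref, alt, gene, plus
    any extra columns) is joined on the variant key; annotation rows whose
    key matches no merged variant are ignored with a warning.

    Returns ``(report, summaries)`` where summaries holds the ``by_gene``,
    ``by_score`` and ``by_type`` count series, each conserving the total
    variant count (``by_gene`` only over annotated variants).
    """
    rows = []
    ordered = sorted(merged, key=lambda m: (-m.confidence, m.key))
    for mv in ordered:
        row = {
            "chrom": mv.key.chrom,
            "pos": mv.key.pos,
            "ref": mv.key.ref,
            "alt": mv.key.alt,
            "type": classify_variant(mv.key).value,
            "confidence": mv.confidence,
            "combos": ",".join(c.label for c in sorted(mv.supporting)),
        }
        rep = mv.representative_annotations
        row["qual"] = rep.qual
        row["dp"] = rep.dp
        for combo, ann in mv.per_combo_annotations:
            row[f"dp_{combo.label}"] = ann.dp
        rows.append(row)
    report = pd.DataFrame(rows)

    if annotations is not None and not report.empty:
        ann = annotations.copy()
        ann["pos"] = ann["pos"].astype(int)
        key_cols = ["chrom", "pos", "ref", "alt"]
        merged_keys = set(map(tuple, report[key_cols].itertuples(index=False)))
        orphan = ~ann[key_cols].apply(tuple, axis=1).isin(merged_keys)
        if orphan.any():
            logger.warning(
                "%d annotation rows match no merged variant; ignored", int(orphan.sum())
            )
            ann = ann[~orphan]
        report = report.merge(ann, on=key_cols, how="left")

    summaries: dict[str, pd.Series] = {}
    if report.empty:
        summaries["by_score"] = pd.Series(dtype=int)
        summaries["by_type"] = pd.Series(dtype=int)
        summaries["by_gene"] = pd.Series(dtype=int)
    else:
        summaries["by_score"] = report["confidence"].value_counts().sort_index()
        summaries["by_type"] = report["type"].value_counts().sort_index()
        if "gene" in report.columns:
            summaries["by_gene"] = report["gene"].dropna().value_counts().sort_index()
        else:
            summaries["by_gene"] = pd.Series(dtype=int)
    return report, summaries


def score_histogram(summary_by_score: pd.Series, path: str) -> None:
    """Write a confidence-score histogram (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(summary_by_score.index.astype(int), summary_by_score.values, color="#4878a8")
    ax.set_xlabel("confidence score")
    ax.set_ylabel("variants")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
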