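"""Readers and writers for the standard formats at the pipeline boundary.

BED target regions, per-combination VCF callsets, SAM alignments, training
indel tables (TSV) and threshold configs (YAML). All parsing of VCF/SAM is
delegated to pysam; this module only maps records onto the package's domain
types and back.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    CallSet,
    ComboId,
    GenomicInterval,
    HomopolymerThresholds,
    ParseError,
    QualityAnnotations,
    TrainingIndel,
    VariantCall,
    VariantKey,
)
from .variants import ReferenceContext, normalize_variant

# ---------------------------------------------------------------------------
# BED

def read_regions(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into 0-based half-open intervals, preserving order.

    Raises :class:`ParseError` naming the offending line for non-integer
    coordinates or start >= end. ``track``/``browser``/``#`` lines are skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_regions(regions: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.name if r.name is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# VCF

_INFO_DEFS = [
    ("DP", 1, "Integer", "Read depth"),
    ("QD", 1, "Float", "Quality by depth"),
    ("FS", 1, "Float", "Phred-scaled Fisher strand bias"),
    ("MQ0", 1, "Integer", "Count of mapping-quality-zero reads"),
    ("ReadPosRankSum", 1, "Float", "Read position rank-sum statistic"),
]

_FILTER_LABELS = [
    "OFF_TARGET",
    "LOW_DP",
    "LOW_QUAL",
    "LOW_QD",
    "HIGH_FS",
    "MQ0_RATIO",
    "SNP_CLUSTER",
    "INDEL_EXPR",
    "DEPTH_RANGE",
    "HP_INDEL",
    "MISSING_DP",
    "MISSING_QUAL",
    "MISSING_QD",
    "MISSING_FS",
    "MISSING_MQ0",
    "MISSING_READPOSRANKSUM",
]


def _vcf_header(
    contigs: Iterable[str],
    combo: Optional[ComboId] = None,
    merged: bool = False,
    extra_filters: Iterable[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in contigs:
        header.contigs.add(name)
    for key, number, vtype, desc in _INFO_DEFS:
        header.info.add(key, number, vtype, desc)
    if merged:
        header.info.add("CONF", 1, "Integer", "Confidence score (supporting combinations)")
        header.info.add("COMBOS", ".", "String", "Supporting aligner_caller combinations")
    for label in list(_FILTER_LABELS) + list(extra_filters):
        if label not in header.filters:
            header.filters.add(label, None, None, f"Failed rule {label}")
    if combo is not None:
        header.add_meta("combo", value=combo.label)
    return header


def _annotations_from_record(rec: pysam.VariantRecord) -> QualityAnnotations:
    info = rec.info

    def _get(key):
        if key in info:
            val = info[key]
            if isinstance(val, tuple):
                val = val[0]
            return val
        return None

    dp = _get("DP")
    mq0 = _get("MQ0")
    return QualityAnnotations(
        qual=None if rec.qual is None else float(rec.qual),
        dp=None if dp is None else int(dp),
        qd=_get("QD"),
        fs=_get("FS"),
        mq0=None if mq0 is None else int(mq0),
        read_pos_rank_sum=_get("ReadPosRankSum"),
    )


def read_callset(
    path: str | os.PathLike,
    combo: Optional[ComboId] = None,
    reference: Optional[ReferenceContext] = None,
    normalize: bool = True,
) -> CallSet:
    """Read one combination's VCF into a :class:`CallSet`.

    Multi-allelic records are split into one call per alternate allele before
    normalization. The combination is taken from the ``##combo=`` header line
    unless given explicitly.
    """
    with pysam.VariantFile(os.fspath(path)) as vcf:
        if combo is None:
            for rec in vcf.header.records:
                if rec.key == "combo":
                    combo = ComboId.from_label(rec.value)
                    break
        if combo is None:
            raise ParseError(f"{path}: no ##combo header line and no combo given")
        calls: list[VariantCall] = []
        seen: set[VariantKey] = set()
        for rec in vcf:
            ann = _annotations_from_record(rec)
            labels = frozenset(f for f in rec.filter.keys() if f != "PASS")
            for alt in rec.alts or ():
                if alt is None or set(alt.upper()) - {"A", "C", "G", "T", "N"}:
                    continue  # symbolic/breakend alleles are out of scope
                key = VariantKey(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                if normalize:
                    key = normalize_variant(key, reference)
                if key in seen:
                    continue
                seen.add(key)
                calls.append(VariantCall(key, ann, combo, labels))
    return CallSet(combo, calls)


def _set_record_info(rec: pysam.VariantRecord, ann: QualityAnnotations) -> None:
    if ann.dp is not None:
        rec.info["DP"] = ann.dp
    if ann.qd is not None:
        rec.info["QD"] = ann.qd
    if ann.fs is not None:
        rec.info["FS"] = ann.fs
    if ann.mq0 is not None:
        rec.info["MQ0"] = ann.mq0
    if ann.read_pos_rank_sum is not None:
        rec.info["ReadPosRankSum"] = ann.read_pos_rank_sum


def write_callset(callset: CallSet, path: str | os.PathLike) -> None:
    """Write a callset as an uncompressed VCF with filter labels in FILTER."""
    contigs = sorted({c.key.chrom for c in callset.calls})
    extra = sorted(
        {lab for c in callset.calls for lab in c.filter_labels} - set(_FILTER_LABELS)
    )
    header = _vcf_header(contigs, combo=callset.combo, extra_filters=extra)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for call in sorted(callset.calls, key=lambda c: c.key):
            rec = out.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
            )
            rec.qual = call.annotations.qual
            _set_record_info(rec, call.annotations)
            if call.filter_labels:
                for label in sorted(call.filter_labels):
                    rec.filter.add(label)
            else:
                rec.filter.add("PASS")
            out.write(rec)


def write_merged_vcf(merged, path: str | os.PathLike) -> None:
    """Write merged variants with INFO CONF and COMBOS tags."""
    contigs = sorted({m.key.chrom for m in merged})
    header = _vcf_header(contigs, merged=True)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for mv in merged:
            rec = out.new_record(
                contig=mv.key.chrom,
                start=mv.key.pos - 1,
                alleles=(mv.key.ref, mv.key.alt),
            )
            rep = mv.representative_annotations
            rec.qual = rep.qual
            if rep.dp is not None:
                rec.info["DP"] = rep.dp
            rec.info["CONF"] = mv.confidence
            rec.info["COMBOS"] = ",".join(c.label for c in sorted(mv.supporting))
            rec.filter.add("PASS")
            out.write(rec)


# ---------------------------------------------------------------------------
# SAM

def read_alignments(path: str | os.PathLike) -> list[AlignedRead]:
    """Read mapped reads from a SAM/BAM file into the minimal read model."""
    op_codes = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            cigar = tuple(
                (op_codes[op], length)
                for op, length in rec.cigartuples
                if op in op_codes
            )
            if not cigar:
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=cigar,
                    mapping_quality=rec.mapping_quality,
                )
            )
    return reads


def write_alignments(
    reads: Sequence[AlignedRead],
    path: str | os.PathLike,
    reference_lengths: Mapping[str, int],
) -> None:
    """Write reads as a plain-text SAM file (sequences emitted as N runs)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        ref_ids = {name: i for i, name in enumerate(reference_lengths)}
        for read in sorted(reads, key=lambda r: (r.chrom, r.pos, r.read_id)):
            seg = pysam.AlignedSegment()
            seg.query_name = read.read_id
            seg.reference_id = ref_ids[read.chrom]
            seg.reference_start = read.pos - 1
            seg.mapping_quality = read.mapping_quality
            op_codes = {"M": 0, "I": 1, "D": 2, "S": 4}
            seg.cigartuples = [(op_codes[op], length) for op, length in read.cigar]
            qlen = sum(length for op, length in read.cigar if op in "MIS")
            seg.query_sequence = "N" * qlen
            seg.flag = 0
            out.write(seg)


# ---------------------------------------------------------------------------
# FASTA

def read_reference(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_reference(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# Training tables and thresholds

_TRAINING_COLUMNS = ["chrom", "pos", "ref", "alt", "label", "var", "frmode"]


def read_training_table(path: str | os.PathLike) -> list[TrainingIndel]:
    """Read a labeled training-indel TSV (chrom, pos, ref, alt, label, var, frmode)."""
    entries: list[TrainingIndel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRAINING_COLUMNS:
            raise ParseError(f"{path}: expected columns {_TRAINING_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TRAINING_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_TRAINING_COLUMNS)} columns")
            chrom, pos, ref, alt, label, var, frmode = fields
            try:
                entries.append(
                    TrainingIndel(
                        site=VariantKey(chrom, int(pos), ref, alt),
                        label=label,
                        var=float(var),
                        frmode=float(frmode),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return entries


def write_training_table(entries: Sequence[TrainingIndel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRAINING_COLUMNS) + "\n")
        for t in entries:
            fh.write(
                f"{t.site.chrom}\t{t.site.pos}\t{t.site.ref}\t{t.site.alt}\t"
                f"{t.label}\t{t.var:.6g}\t{t.frmode:.6g}\n"
            )


def read_thresholds(path: str | os.PathLike) -> HomopolymerThresholds:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return HomopolymerThresholds(
        max_var=float(data["max_var"]), min_frmode=float(data["min_frmode"])
    )


def write_thresholds(thresholds: HomopolymerThresholds, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"max_var": thresholds.max_var, "min_frmode": thresholds.min_frmode},
            fh,
            default_flow_style=False,
        )
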