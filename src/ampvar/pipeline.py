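"""End-to-end pipeline: region filter -> quality filters -> homopolymer
indel filter -> merge + confidence score -> report.

The pipeline is deterministic: given identical inputs it writes
byte-identical outputs, and a manifest accounts for every input variant as
retained or rejected with a reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import formats
from .filters import (
    DepthFilterConfig,
    IndelFilterConfig,
    SnpFilterConfig,
    apply_union_retention,
    label_callset,
    region_filter,
)
from .homopolymer import filter_homopolymer_indels
from .merge import merge, score_distribution
from .model import (
    AmpvarError,
    CallSet,
    ComboId,
    HomopolymerThresholds,
    VariantKey,
)
from .report import amplicon_coverage, build_report
from .variants import ReferenceContext, is_indel_like

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration mapping inputs to declared combinations."""

    callsets: dict[str, str]  # combo label -> VCF path
    alignments: dict[str, str]  # aligner -> SAM/BAM path
    regions: str
    out_dir: str
    aligners: tuple[str, ...] = ("bwa", "bowtie2", "nextgenmap")
    callers: tuple[str, ...] = ("gatk", "samtools")
    reference: Optional[str] = None
    annotation: Optional[str] = None
    thresholds: HomopolymerThresholds = field(default_factory=HomopolymerThresholds)
    snp_filter: SnpFilterConfig = field(default_factory=SnpFilterConfig)
    indel_filter: IndelFilterConfig = field(default_factory=IndelFilterConfig)
    depth_filter: DepthFilterConfig = field(default_factory=DepthFilterConfig)
    hp_mode: str = "exact"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            data = yaml.safe_load(fh)

        def _resolve(p: Optional[str]) -> Optional[str]:
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        kwargs: dict = {
            "callsets": {k: _resolve(v) for k, v in data["callsets"].items()},
            "alignments": {k: _resolve(v) for k, v in data.get("alignments", {}).items()},
            "regions": _resolve(data["regions"]),
            "out_dir": _resolve(data["out_dir"]),
            "reference": _resolve(data.get("reference")),
            "annotation": _resolve(data.get("annotation")),
        }
        if "aligners" in data:
            kwargs["aligners"] = tuple(data["aligners"])
        if "callers" in data:
            kwargs["callers"] = tuple(data["callers"])
        if "thresholds" in data:
            kwargs["thresholds"] = HomopolymerThresholds(**data["thresholds"])
        for key, cfg_cls in (
            ("snp_filter", SnpFilterConfig),
            ("indel_filter", IndelFilterConfig),
            ("depth_filter", DepthFilterConfig),
        ):
            if key in data:
                kwargs[key] = cfg_cls(**data[key])
        if "hp_mode" in data:
            kwargs["hp_mode"] = data["hp_mode"]
        return cls(**kwargs)

    def validate(self) -> None:
        declared = {f"{a}_{c}" for a in self.aligners for c in self.callers}
        for label in self.callsets:
            if label not in declared:
                raise AmpvarError(f"callset declared for unknown combination {label!r}")
        for aligner in self.alignments:
            if aligner not in self.aligners:
                raise AmpvarError(f"alignment declared for unknown aligner {aligner!r}")
        missing = [
            p
            for p in [self.regions, *self.callsets.values(), *self.alignments.values()]
            if p and not Path(p).exists()
        ]
        if missing:
            raise AmpvarError(f"missing input files: {missing}")


def _key_str(key: VariantKey) -> str:
    return f"{key.chrom}:{key.pos}:{key.ref}>{key.alt}"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the run directory; returns the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference_ctx = None
    if cfg.reference:
        sequences = formats.read_reference(cfg.reference)
        # single-contig panels are the common case; multi-contig references
        # fall back to per-call context lookup below
        contexts = {
            name: ReferenceContext(name, 1, seq) for name, seq in sequences.items()
        }
    else:
        contexts = {}

    regions = formats.read_regions(cfg.regions)
    manifest: dict = {"stages": {}, "variants": {}}

    callsets: list[CallSet] = []
    for label, path in sorted(cfg.callsets.items()):
        combo = ComboId.from_label(label)
        ctx = None
        cs = formats.read_callset(path, combo=combo)
        if contexts:
            calls = []
            from .variants import normalize_variant

            for call in cs.calls:
                ctx = contexts.get(call.key.chrom)
                key = normalize_variant(call.key, ctx)
                calls.append(
                    type(call)(key, call.annotations, call.combo, call.filter_labels)
                )
            cs = CallSet(combo, _dedupe(calls))
        callsets.append(cs)
        for call in cs.calls:
            manifest["variants"].setdefault(label, {})[_key_str(call.key)] = "input"

    # stage 1: region filter
    stage1 = []
    for cs in callsets:
        kept = region_filter(cs.calls, regions)
        kept_keys = {c.key for c in kept}
        for call in cs.calls:
            status = "retained" if call.key in kept_keys else "OFF_TARGET"
            manifest["variants"][cs.combo.label][_key_str(call.key)] = status
        stage1.append(CallSet(cs.combo, kept))
    manifest["stages"]["region_filter"] = {
        cs.combo.label: len(cs.calls) for cs in stage1
    }
    logger.info("region filter: %s", manifest["stages"]["region_filter"])

    # stage 2: quality expressions + union retention per caller group
    labeled = [
        label_callset(cs, cfg.snp_filter, cfg.indel_filter, cfg.depth_filter)
        for cs in stage1
    ]
    for cs in labeled:
        formats.write_callset(cs, out / f"labeled_{cs.combo.label}.vcf")
    stage2 = apply_union_retention(labeled)
    for before, after in zip(labeled, stage2):
        kept_keys = after.keys()
        for call in before.calls:
            if call.key not in kept_keys:
                reason = ",".join(sorted(call.filter_labels)) or "QUALITY_FILTER"
                manifest["variants"][before.combo.label][_key_str(call.key)] = reason
    manifest["stages"]["quality_filter"] = {
        cs.combo.label: len(cs.calls) for cs in stage2
    }
    logger.info("quality filter: %s", manifest["stages"]["quality_filter"])

    # stage 3: homopolymer indel filter
    reads_by_aligner = {
        aligner: formats.read_alignments(path)
        for aligner, path in sorted(cfg.alignments.items())
    }
    candidate_sites = sorted(
        {c.key for cs in stage2 for c in cs.calls if is_indel_like(c.key)}
    )
    ctx_for_hp = None
    if contexts and candidate_sites:
        ctx_for_hp = contexts.get(candidate_sites[0].chrom)
    verdicts = filter_homopolymer_indels(
        candidate_sites,
        reads_by_aligner,
        cfg.thresholds,
        reference=ctx_for_hp,
        mode=cfg.hp_mode,  # type: ignore[arg-type]
    )
    rejected = {site for site, v in verdicts.items() if not v.passed}
    stage3 = []
    for cs in stage2:
        kept = [c for c in cs.calls if c.key not in rejected]
        for call in cs.calls:
            if call.key in rejected:
                manifest["variants"][cs.combo.label][_key_str(call.key)] = "HP_INDEL"
        stage3.append(CallSet(cs.combo, kept))
    manifest["stages"]["homopolymer_filter"] = {
        "candidates": len(candidate_sites),
        "rejected": sorted(_key_str(s) for s in rejected),
    }
    logger.info(
        "homopolymer filter: %d candidates, %d rejected",
        len(candidate_sites),
        len(rejected),
    )

    # stage 4: merge + confidence score
    merged = merge(stage3)
    formats.write_merged_vcf(merged, out / "merged.vcf")
    manifest["stages"]["merge"] = {
        "variants": len(merged),
        "score_distribution": {
            str(k): v for k, v in sorted(score_distribution(merged).items())
        },
    }
    logger.info("merged %d variants", len(merged))

    # stage 5: report + coverage
    annotations = None
    if cfg.annotation:
        import pandas as pd

        annotations = pd.read_csv(cfg.annotation, sep="\t")
    report, summaries = build_report(merged, annotations)
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    coverage = amplicon_coverage(reads_by_aligner, regions)
    coverage.to_csv(out / "coverage.tsv", sep="\t")
    for name, series in summaries.items():
        series.rename("count").to_csv(out / f"summary_{name}.tsv", sep="\t")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _dedupe(calls):
    seen = set()
    out = []
    for call in calls:
        if call.key in seen:
            continue
        seen.add(call.key)
        out.append(call)
    return out
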