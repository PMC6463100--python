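"""Normalize variant representations and apply region + quality filters.

Different callers write the same indel in different ways; normalization
(trim + left-align) makes them comparable, then the region filter and the
GATK-style quality expressions label what should not be trusted.
"""

from ampvar import (
    ComboId,
    GenomicInterval,
    QualityAnnotations,
    ReferenceContext,
    SnpFilterConfig,
    VariantCall,
    VariantKey,
    evaluate_snp_filters,
    normalize_variant,
    region_filter,
)

# the same 1-bp deletion in a T-run, written at two different placements
ref = ReferenceContext("chr17", 7578470, "GTTTTA")
right = VariantKey("chr17", 7578473, "TT", "T")
left = VariantKey("chr17", 7578470, "GT", "G")
print("right-shifted ->", normalize_variant(right, ref))
print("left-shifted  ->", normalize_variant(left, ref))
print("identical after normalization:", normalize_variant(right, ref) == normalize_variant(left, ref))

# region filter: only calls inside the amplicon panel survive
panel = [GenomicInterval("chr17", 7578000, 7578500, "TP53_EX5")]
calls = [
    VariantCall(VariantKey("chr17", 7578300, "A", "G"), QualityAnnotations(qual=900.0, dp=400, qd=12.0, fs=3.0, mq0=0), ComboId("bwa", "gatk")),
    VariantCall(VariantKey("chr17", 7600000, "C", "T"), QualityAnnotations(qual=900.0, dp=400, qd=12.0, fs=3.0, mq0=0), ComboId("bwa", "gatk")),
]
on_target = region_filter(calls, panel)
print(f"\n{len(on_target)} of {len(calls)} calls fall inside the panel")

# quality expressions: a shallow call fails DP < 5, and the Fisher-strand
# threshold is aligner-specific (590 for bwa, 60 elsewhere)
shallow = VariantCall(
    VariantKey("chr17", 7578300, "A", "G"),
    QualityAnnotations(qual=60.0, dp=4, qd=1.0, fs=100.0, mq0=0),
    ComboId("bowtie2", "gatk"),
)
verdict = evaluate_snp_filters(shallow, SnpFilterConfig())
print("shallow bowtie2 call labeled with:", sorted(verdict.reasons))
# LOW_DP (4 < 5) and HIGH_FS (100 > 60); the identical call from bwa would
# pass the FS rule because bwa's threshold is 590
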