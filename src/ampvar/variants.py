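"""Variant normalization and classification.

Callsets from different callers represent the same indel in different ways
(padded alleles, right-shifted placements in repeat runs). Merging by exact
key therefore requires a canonical representation first: trim shared bases,
then — when reference context is available — shift indels to their leftmost
equivalent placement, the standard left-alignment convention.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from .model import ContractError, VariantKey


class VariantType(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"
    MNP = "MNP"
    COMPLEX = "COMPLEX"


class ReferenceContext:
    """A reference snippet anchored at a 1-based genomic offset.

    ``base(pos)`` returns the reference base at 1-based position ``pos`` or
    None outside the snippet, so left-shifting stops at the snippet edge.
    """

    def __init__(self, chrom: str, start_pos: int, sequence: str):
        self.chrom = chrom
        self.start_pos = start_pos
        self.sequence = sequence.upper()

    def base(self, pos: int) -> Optional[str]:
        idx = pos - self.start_pos
        if 0 <= idx < len(self.sequence):
            return self.sequence[idx]
        return None

    def slice(self, pos: int, length: int) -> Optional[str]:
        idx = pos - self.start_pos
        if idx < 0 or idx + length > len(self.sequence):
            return None
        return self.sequence[idx : idx + length]


def _trim(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    # shared suffix first, then shared prefix keeping >= 1 base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def normalize_variant(
    key: VariantKey, reference: Optional[ReferenceContext] = None
) -> VariantKey:
    """Return the canonical representation of ``key``.

    Shared trailing bases are trimmed, then shared leading bases (always
    keeping at least one anchor base for indels). With ``reference`` supplied,
    pure insertions/deletions are additionally shifted to their leftmost
    equivalent position. Idempotent.

    Raises ValueError if ref == alt after trimming (not a variant; the
    VariantKey constructor enforces this).
    """
    ref, alt, pos = key.ref.upper(), key.alt.upper(), key.pos
    ref, alt, pos = _trim(ref, alt, pos)

    is_indel = len(ref) != len(alt)
    if reference is not None and is_indel and (len(ref) == 1 or len(alt) == 1):
        # canonical anchored form: ref[0] == alt[0], one side length 1
        if ref[0] == alt[0]:
            seq = ref[1:] if len(ref) > 1 else alt[1:]
            while pos > 1:
                anchor = reference.base(pos)
                prev = reference.base(pos - 1)
                if anchor is None or prev is None or anchor != seq[-1]:
                    break
                # rotate right: the anchor base becomes the head of the
                # varying sequence and the placement moves one base left
                seq = anchor + seq[:-1]
                pos -= 1
            anchor = reference.base(pos) or ref[0]
            if len(ref) > 1:
                ref, alt = anchor + seq, anchor
            else:
                ref, alt = anchor, anchor + seq
            ref, alt, pos = _trim(ref, alt, pos)

    return VariantKey(key.chrom, pos, ref, alt)


def classify_variant(key: VariantKey) -> VariantType:
    """Classify a normalized key as SNP / INS / DEL / MNP / COMPLEX."""
    ref, alt = key.ref, key.alt
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNP
    if len(alt) > len(ref) and alt.startswith(ref):
        return VariantType.INS
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantType.DEL
    if len(ref) == len(alt):
        return VariantType.MNP
    return VariantType.COMPLEX


def is_snp_like(key: VariantKey) -> bool:
    return classify_variant(key) in (VariantType.SNP, VariantType.MNP)


def is_indel_like(key: VariantKey) -> bool:
    return classify_variant(key) in (
        VariantType.INS,
        VariantType.DEL,
        VariantType.COMPLEX,
    )


def require_snp_like(key: VariantKey) -> None:
    if not is_snp_like(key):
        raise ContractError(f"expected SNP/MNP, got {classify_variant(key).value}")


def require_indel_like(key: VariantKey) -> None:
    if not is_indel_like(key):
        raise ContractError(f"expected indel, got {classify_variant(key).value}")
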