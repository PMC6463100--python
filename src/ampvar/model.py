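"""Domain types for amplicon variant filtering and merging.

Coordinate conventions: :class:`VariantKey` positions are 1-based (VCF
dialect); :class:`GenomicInterval` is 0-based half-open (BED dialect).
Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

VALID_BASES = frozenset("ACGTN")

DEFAULT_ALIGNERS = ("bwa", "bowtie2", "nextgenmap")
DEFAULT_CALLERS = ("gatk", "samtools")


class AmpvarError(Exception):
    """Base class for package errors."""


class ParseError(AmpvarError):
    """Malformed input file content."""


class ContractError(AmpvarError):
    """An operation was invoked outside its stated precondition."""


class NoEventsError(AmpvarError):
    """Indel-length statistics requested for a site with no indel events."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A target region (amplicon): 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def contains(self, pos0: int) -> bool:
        """True if 0-based position ``pos0`` lies inside the interval."""
        return self.start <= pos0 < self.end

    def overlaps_span(self, start0: int, end0: int) -> bool:
        """True if the 0-based half-open span [start0, end0) overlaps by >= 1 base."""
        return start0 < self.end and end0 > self.start


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized (chrom, pos, ref, alt) identity; pos is the 1-based anchor base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}): not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= VALID_BASES:
                raise ValueError(f"allele {allele!r} contains characters outside ACGTN")


@dataclass(frozen=True)
class QualityAnnotations:
    """Per-call quality annotations; ``None`` means the caller did not emit the field.

    Absent is distinct from zero: filter expressions treat a missing field as a
    failing sub-expression.
    """

    qual: Optional[float] = None
    dp: Optional[int] = None
    qd: Optional[float] = None
    fs: Optional[float] = None
    mq0: Optional[int] = None
    read_pos_rank_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("dp must be >= 0")
        if self.mq0 is not None and self.mq0 < 0:
            raise ValueError("mq0 must be >= 0")
        if self.fs is not None and self.fs < 0:
            raise ValueError("fs must be >= 0")


@dataclass(frozen=True, order=True)
class ComboId:
    """One (aligner, caller) combination, e.g. (bwa, gatk)."""

    aligner: str
    caller: str

    @property
    def label(self) -> str:
        return f"{self.aligner}_{self.caller}"

    @classmethod
    def from_label(cls, label: str) -> "ComboId":
        aligner, _, caller = label.partition("_")
        if not aligner or not caller:
            raise ValueError(f"combo label must be '<aligner>_<caller>', got {label!r}")
        return cls(aligner, caller)


def default_combos(
    aligners: Iterable[str] = DEFAULT_ALIGNERS,
    callers: Iterable[str] = DEFAULT_CALLERS,
) -> list[ComboId]:
    """The full aligner x caller grid (3 x 2 = 6 by default)."""
    return [ComboId(a, c) for a in aligners for c in callers]


@dataclass(frozen=True)
class VariantCall:
    """One variant as emitted by one (aligner, caller) combination."""

    key: VariantKey
    annotations: QualityAnnotations = field(default_factory=QualityAnnotations)
    combo: ComboId = ComboId("bwa", "gatk")
    filter_labels: frozenset[str] = frozenset()

    def with_labels(self, labels: Iterable[str]) -> "VariantCall":
        return replace(self, filter_labels=frozenset(labels))


@dataclass
class CallSet:
    """All calls from one combination; keys are unique within a callset."""

    combo: ComboId
    calls: list[VariantCall]

    def __post_init__(self) -> None:
        keys = [c.key for c in self.calls]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate VariantKey within callset {self.combo.label}")

    def keys(self) -> set[VariantKey]:
        return {c.key for c in self.calls}


#: CIGAR operations the read model understands.
CIGAR_OPS = frozenset("MIDS")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal mapped-read model: enough CIGAR structure to walk indel events."""

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost aligned reference position
    cigar: tuple[tuple[str, int], ...]
    mapping_quality: int = 60

    def __post_init__(self) -> None:
        if not self.cigar:
            raise ValueError("cigar must be non-empty")
        for op, length in self.cigar:
            if op not in CIGAR_OPS:
                raise ValueError(f"unsupported CIGAR op {op!r}")
            if length < 1:
                raise ValueError("CIGAR lengths must be >= 1")

    @property
    def reference_span(self) -> tuple[int, int]:
        """1-based inclusive span [pos, end] consumed on the reference (M and D)."""
        consumed = sum(length for op, length in self.cigar if op in "MD")
        return self.pos, self.pos + consumed - 1

    def indel_events(self) -> list[tuple[int, int]]:
        """All I/D events as (anchor_pos, signed_length).

        ``anchor_pos`` is the 1-based reference position of the last aligned
        base before the event — the same anchor a normalized VCF key uses.
        Insertions are positive, deletions negative.
        """
        events = []
        ref = self.pos
        for op, length in self.cigar:
            if op == "M":
                ref += length
            elif op == "D":
                events.append((ref - 1, -length))
                ref += length
            elif op == "I":
                events.append((ref - 1, length))
            # S consumes neither reference nor anchor
        return events


@dataclass(frozen=True)
class HomopolymerThresholds:
    """(maxVar, minFrmode) rejection thresholds for homopolymer indel candidates.

    Defaults are the calibrated operating point: a candidate is rejected when,
    for at least one aligner, var > max_var AND frmode < min_frmode (both
    strict).
    """

    max_var: float = 0.055
    min_frmode: float = 0.9790

    def __post_init__(self) -> None:
        if self.max_var < 0:
            raise ValueError("max_var must be >= 0")
        if not (0 < self.min_frmode <= 1):
            raise ValueError("min_frmode must be in (0, 1]")


@dataclass(frozen=True)
class TrainingIndel:
    """A labeled training indel with its precomputed var/frmode statistics."""

    site: VariantKey
    label: str  # "TP" or "FP"
    var: float
    frmode: float

    def __post_init__(self) -> None:
        if self.label not in ("TP", "FP"):
            raise ValueError(f"label must be TP or FP, got {self.label!r}")
        if self.var < 0:
            raise ValueError("var must be >= 0")
        if not (0 < self.frmode <= 1):
            raise ValueError("frmode must be in (0, 1]")
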