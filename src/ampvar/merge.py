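"""Ensemble merging of aligner x caller callsets with a confidence score.

Each variant surviving the filters is supported by some subset of the
declared (aligner, caller) combinations; the size of that subset is its
confidence score (1..6 in the default 3 aligner x 2 caller grid). The score
prioritizes variants — more independent pipelines agreeing means more
confidence — but is not an elimination criterion.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from .model import CallSet, ComboId, ContractError, QualityAnnotations, VariantKey


@dataclass(frozen=True)
class MergedVariant:
    key: VariantKey
    supporting: frozenset[ComboId]
    per_combo_annotations: tuple[tuple[ComboId, QualityAnnotations], ...]

    def __post_init__(self) -> None:
        if not self.supporting:
            raise ValueError("supporting combination set must be non-empty")

    @property
    def confidence(self) -> int:
        """Number of supporting combinations; never stored independently."""
        return len(self.supporting)

    def annotations_for(self, combo: ComboId) -> QualityAnnotations | None:
        for c, ann in self.per_combo_annotations:
            if c == combo:
                return ann
        return None

    @property
    def representative_annotations(self) -> QualityAnnotations:
        """Aggregate across combos: max QUAL, median DP (rounded to int)."""
        quals = [a.qual for _, a in self.per_combo_annotations if a.qual is not None]
        dps = [a.dp for _, a in self.per_combo_annotations if a.dp is not None]
        return QualityAnnotations(
            qual=max(quals) if quals else None,
            dp=int(round(statistics.median(dps))) if dps else None,
        )


def merge(callsets: Sequence[CallSet]) -> list[MergedVariant]:
    """Merge callsets into one variant per distinct key, sorted genomically.

    Supporting combinations are exactly those whose callset contains the
    key; the result is invariant under permutation of the input callsets.
    Duplicate combination ids are rejected.
    """
    combos = [cs.combo for cs in callsets]
    if len(set(combos)) != len(combos):
        raise ContractError("duplicate ComboId across callsets")

    by_key: dict[VariantKey, dict[ComboId, QualityAnnotations]] = {}
    for cs in callsets:
        for call in cs.calls:
            by_key.setdefault(call.key, {})[call.combo] = call.annotations

    merged = []
    for key in sorted(by_key):
        support = by_key[key]
        merged.append(
            MergedVariant(
                key=key,
                supporting=frozenset(support),
                per_combo_annotations=tuple(sorted(support.items())),
            )
        )
    return merged


def score_distribution(merged: Sequence[MergedVariant]) -> dict[int, int]:
    """Count variants per confidence score; counts sum to ``len(merged)``."""
    dist: dict[int, int] = {}
    for mv in merged:
        dist[mv.confidence] = dist.get(mv.confidence, 0) + 1
    return dist
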