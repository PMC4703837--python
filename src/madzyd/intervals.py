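"""Genomic interval primitives and developmental stage ordering.

All coordinates in the package are 0-based, half-open. Converters to or
from 1-based formats are the only place offsets change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

#: Ordered developmental stage tokens. Stage 11 is the stage at which
#: transcription-blocked (alpha-amanitin) embryos are compared with controls.
STAGES = ("8", "9", "10.5", "11", "12", "12.5", "16", "30")
STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}
AMANITIN_STAGE = "11"


def stage_index(stage: str) -> int:
    """Position of a stage token in the developmental order."""
    stage = str(stage)
    if stage not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stage!r}; known stages: {STAGES}")
    return STAGE_ORDER[stage]


def stage_le(a: str, b: str) -> bool:
    """True when stage ``a`` is at or before stage ``b``."""
    return stage_index(a) <= stage_index(b)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    scaffold
        Sequence (scaffold/chromosome) name; non-empty.
    start, end
        0-based half-open coordinates with ``end > start >= 0``.
    strand
        One of ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold name must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSSRecord:
    """Canonical transcription start site of one gene."""

    gene_id: str
    scaffold: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")

    def promoter(self, upstream: int, downstream: int | None = None) -> GenomicInterval:
        """Strand-aware promoter window around the TSS.

        ``promoter(250)`` gives the symmetric +/-250 bp window; asymmetric
        windows pass ``downstream`` explicitly (both measured in the
        direction of transcription).
        """
        if downstream is None:
            downstream = upstream
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.scaffold, max(0, start), max(1, end), self.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or bookended intervals into their union.

    Intervals sharing even one base are merged; intervals that abut with a
    gap of exactly 0 are merged too, matching peak-caller merge semantics.
    Output is coordinate-sorted and non-overlapping.
    """
    items = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].scaffold == iv.scaffold and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.scaffold, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.scaffold, iv.start, iv.end))
    return merged


def merge_peak_sets(sets: Sequence[Iterable[GenomicInterval]]) -> list[GenomicInterval]:
    """Union of several peak sets with overlapping/adjacent peaks coalesced.

    This is the "merged peak set" used to avoid bias caused by peak calling
    differences between samples: downstream differential statistics are run
    on the union so every region is quantified in every sample.
    """
    pooled: list[GenomicInterval] = []
    for s in sets:
        pooled.extend(s)
    return merge_intervals(pooled)


def restrict_scaffolds(items, whitelist) -> list:
    """Keep only items on whitelisted scaffolds, preserving order.

    Mirrors the restriction of the analysis to chromosome-sized scaffolds.
    Items must expose a ``scaffold`` attribute.
    """
    whitelist = set(whitelist)
    if not whitelist:
        raise ValueError("scaffold whitelist must be non-empty")
    return [it for it in items if it.scaffold in whitelist]


def interval_union_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))
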