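"""Genomic-interval data model and set operations.

All coordinates are 0-based, half-open (BED convention). Two intervals
overlap iff they share at least one base; half-open adjacency
(``a.end == b.start``) is not an overlap. These primitives underlie every
downstream stage: peak-presence calls, replicate reproducibility, TSS
assignment, and Hi-C anchor matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .errors import NoTSSOnChromosome

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TSSRecord",
    "overlaps",
    "intersect_presence",
    "replicate_reproducible",
    "nearest_tss",
    "window_around",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    Invariants ``0 <= start < end`` and a non-empty chromosome name are
    enforced at construction; downstream code never re-validates.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.name or "")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site (single 0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


class IntervalSet:
    """An indexed, deterministically ordered collection of intervals.

    Iteration order is sorted by (chrom, start, end, name). Overlap queries
    run in O(log n + k) against a per-chromosome interval tree built lazily
    on first query.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval.sort_key)
        )
        self.label = label
        self._trees: dict[str, IntervalTree] | None = None

    def _index(self) -> dict[str, IntervalTree]:
        # tree payloads are positional indices, not the intervals themselves:
        # duplicate spans (e.g. identical tags) must stay distinct members
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
            self._trees = trees
        return self._trees

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals sharing >=1 base with ``query``, sorted."""
        tree = self._index().get(query.chrom)
        if tree is None:
            return []
        hits = [self.intervals[hit.data] for hit in tree.overlap(query.start, query.end)]
        return sorted(hits, key=GenomicInterval.sort_key)

    def overlaps_any(self, query: GenomicInterval) -> bool:
        tree = self._index().get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))

    def count_overlapping(self, query: GenomicInterval) -> int:
        tree = self._index().get(query.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(query.start, query.end))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open spans share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def intersect_presence(query: IntervalSet, subject: IntervalSet) -> list[bool]:
    """Per-query presence vector: does query interval i hit >=1 subject?

    This is the "+/-" track-status call used throughout enhancer
    classification (e.g. is a region ATAC+ in a given condition).
    """
    return [subject.overlaps_any(iv) for iv in query]


def replicate_reproducible(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Regions called in both replicates.

    Returns the rep1 intervals that overlap >=1 rep2 interval; rep1 supplies
    the coordinates (documented convention — the rule is "called in both",
    not a span merge).
    """
    kept = [iv for iv in rep1 if rep2.overlaps_any(iv)]
    return IntervalSet(kept, label=rep1.label)


def nearest_tss(
    region: GenomicInterval, tss_table: Sequence[TSSRecord]
) -> tuple[str, int]:
    """Assign a region to the closest TSS.

    Selection minimizes |region midpoint - tss|; ties go to the
    lexicographically smaller gene_id. The reported distance is 0 when the
    TSS falls inside the region span; otherwise it is the midpoint distance,
    signed + if the midpoint lies downstream of the TSS in the gene's strand
    orientation and - if upstream.
    """
    mid = region.midpoint
    best: TSSRecord | None = None
    best_d = None
    for rec in tss_table:
        if rec.chrom != region.chrom:
            continue
        d = abs(mid - rec.tss)
        if best is None or d < best_d or (d == best_d and rec.gene_id < best.gene_id):
            best, best_d = rec, d
    if best is None:
        raise NoTSSOnChromosome(f"no TSS on {region.chrom}")
    if region.start <= best.tss < region.end:
        return best.gene_id, 0
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return best.gene_id, signed


def window_around(anchor_pos: int, half_width: int, chrom: str = "chr") -> GenomicInterval:
    """Symmetric window ``[anchor - hw, anchor + hw)``, clipped at 0.

    The two windows the analysis uses are ±2 kb around a TSS (promoter /
    TSS-accessibility window) and ±10 kb around a peak center (heatmap
    interval).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    return GenomicInterval(chrom, max(0, anchor_pos - half_width), anchor_pos + half_width)
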