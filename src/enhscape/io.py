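"""Readers and writers for the on-disk formats the pipeline touches.

Interchange formats are deliberately plain text: BED3/BED6 for peak and
tag tracks, BED6 for TSS tables (start = tss, end = tss + 1, strand in
column 6), BEDPE for significant Hi-C interactions, and TSV for the
replicate expression matrix. Readers validate and reject malformed records
with the offending line number; they never silently repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .intervals import GenomicInterval, IntervalSet, TSSRecord

log = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "ExpressionTable",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "read_bedpe",
    "write_bedpe",
    "read_expression",
    "write_expression",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_int(text: str, what: str, path, lineno) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", path, lineno) from None


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    Column 4 (name) and 5 (score) are kept when present; strand is ignored
    for plain interval tracks (peaks act strand-agnostically).
    """
    intervals = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"expected >=3 tab-separated columns, got {len(cols)}", path, lineno)
        chrom = cols[0]
        start = _parse_int(cols[1], "start", path, lineno)
        end = _parse_int(cols[2], "end", path, lineno)
        name = cols[3] if len(cols) > 3 and cols[3] not in (".", "") else None
        score = None
        if len(cols) > 4 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                raise ParseError(f"non-numeric score: {cols[4]!r}", path, lineno) from None
        try:
            intervals.append(GenomicInterval(chrom, start, end, name, score))
        except ValueError as exc:
            raise ParseError(str(exc), path, lineno) from None
    return IntervalSet(intervals, label=label or Path(path).stem)


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a stranded TSS table (BED6 with start=tss, end=tss+1)."""
    records: list[TSSRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"TSS table needs 6 columns, got {len(cols)}", path, lineno)
        chrom = cols[0]
        tss = _parse_int(cols[1], "tss", path, lineno)
        gene_id, strand = cols[3], cols[5]
        if gene_id in seen:
            raise ParseError(f"duplicate gene_id {gene_id!r}", path, lineno)
        seen.add(gene_id)
        try:
            records.append(TSSRecord(gene_id, chrom, tss, strand))
        except ValueError as exc:
            raise ParseError(str(exc), path, lineno) from None
    return records


def write_tss_table(path: str | Path, records: Iterable[TSSRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t.\t{rec.strand}\n")


@dataclass(frozen=True)
class Interaction:
    """One binned significant Hi-C contact.

    Anchors are resolution-aligned bins in canonical order (anchor1 before
    anchor2 by chrom, then start).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    condition: str
    score: float = 0.0

    def canonical(self) -> "Interaction":
        k1 = (self.anchor1.chrom, self.anchor1.start)
        k2 = (self.anchor2.chrom, self.anchor2.start)
        if k2 < k1:
            return replace(self, anchor1=self.anchor2, anchor2=self.anchor1)
        return self

    @property
    def is_cis(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


def _snap_bin(chrom: str, start: int, resolution: int) -> GenomicInterval:
    b = (start // resolution) * resolution
    return GenomicInterval(chrom, b, b + resolution)


def read_bedpe(
    path: str | Path, hic_resolution: int, condition: str = ""
) -> list[Interaction]:
    """Read a BEDPE interaction table, snapping anchors to resolution bins.

    Anchor starts are floored to the bin grid and anchor order normalized.
    Inputs whose spans are not already bin-sized are accepted with a logged
    resolution-mismatch note. A missing score column yields score 0.
    """
    interactions: list[Interaction] = []
    mismatches = 0
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"BEDPE needs >=6 columns, got {len(cols)}", path, lineno)
        c1, c2 = cols[0], cols[3]
        s1 = _parse_int(cols[1], "start1", path, lineno)
        e1 = _parse_int(cols[2], "end1", path, lineno)
        s2 = _parse_int(cols[4], "start2", path, lineno)
        e2 = _parse_int(cols[5], "end2", path, lineno)
        if e1 <= s1 or e2 <= s2:
            raise ParseError("inverted anchor span", path, lineno)
        if (e1 - s1 != hic_resolution or s1 % hic_resolution
                or e2 - s2 != hic_resolution or s2 % hic_resolution):
            mismatches += 1
        score = 0.0
        if len(cols) > 7 and cols[7] not in (".", ""):
            try:
                score = float(cols[7])
            except ValueError:
                raise ParseError(f"non-numeric score: {cols[7]!r}", path, lineno) from None
        inter = Interaction(
            _snap_bin(c1, s1, hic_resolution),
            _snap_bin(c2, s2, hic_resolution),
            condition=condition,
            score=score,
        ).canonical()
        interactions.append(inter)
    if mismatches:
        log.warning(
            "%s: %d interaction(s) not aligned to %d bp bins; snapped to the grid",
            path, mismatches, hic_resolution,
        )
    return interactions


def write_bedpe(path: str | Path, interactions: Iterable[Interaction]) -> None:
    with open(path, "w") as fh:
        for it in interactions:
            a, b = it.anchor1, it.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t.\t{it.score:g}\n"
            )


class ExpressionTable:
    """Replicate RPKM matrix (genes x replicate columns).

    Replicate columns are named ``<condition>_<rep>``; the condition label
    is everything before the final underscore. Every condition must have at
    least two replicate columns, values must be non-negative, and gene ids
    unique.
    """

    def __init__(self, gene_ids: Sequence[str], columns: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(columns)):
            raise ValueError("values shape does not match gene_ids x columns")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene_ids")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("RPKM values must be finite and non-negative")
        self.gene_ids = list(gene_ids)
        self.columns = list(columns)
        self.values = values
        self.condition_labels = [c.rsplit("_", 1)[0] for c in columns]
        counts: dict[str, int] = {}
        for lab in self.condition_labels:
            counts[lab] = counts.get(lab, 0) + 1
        bad = [c for c, n in counts.items() if n < 2]
        if bad:
            raise ValueError(f"condition(s) with <2 replicates: {bad}")
        self.conditions = list(dict.fromkeys(self.condition_labels))

    def condition_matrix(self, condition: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.condition_labels) if lab == condition]
        if not idx:
            raise KeyError(f"condition {condition!r} not in table")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.columns)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a replicate RPKM TSV (first column gene_id, headers <cond>_<rep>)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"cannot read expression TSV: {exc}", path) from None
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"duplicate gene row {dup!r}", path)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError("non-numeric expression value", path)
    if np.any(values < 0):
        raise ParseError("negative RPKM value", path)
    try:
        return ExpressionTable(list(frame.index.astype(str)), list(frame.columns), values)
    except ValueError as exc:
        raise ParseError(str(exc), path) from None


def write_expression(path: str | Path, table: ExpressionTable) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format="%.6g")
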