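"""Tag-level signal quantification.

Peak intensities are normalized as tags per 10 million reads (RP10M) of
the original library: value = overlapping-tag count x 1e7 / library_size.
Profile matrices subdivide a symmetric window around each anchor into
equal bins; each tag contributes to the bin containing its midpoint, so
row sums are additive with whole-window counts (exactly so for point
tags such as insertion/cut sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RP10M_SCALE
from .errors import BinningError, EmptyLibrary
from .intervals import GenomicInterval, IntervalSet

__all__ = ["SignalVector", "rp10m", "profile_matrix"]


@dataclass(frozen=True)
class SignalVector:
    """RP10M signal per region, with the library size it was scaled by."""

    region_ids: tuple[str, ...]
    values: np.ndarray
    library_size: int

    def __post_init__(self):
        if self.library_size <= 0:
            raise EmptyLibrary("library_size must be > 0")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")


def rp10m(
    regions: IntervalSet, tags: IntervalSet, library_size: int | None = None
) -> SignalVector:
    """Tags-per-10-million signal over a set of regions.

    ``library_size`` defaults to the number of tags supplied; pass the
    original library size when the tag file is a subset.
    """
    if library_size is None:
        library_size = len(tags)
    if library_size <= 0:
        raise EmptyLibrary("library_size must be > 0")
    if library_size < len(tags):
        raise ValueError("library_size smaller than the number of tags provided")
    ids = tuple(
        iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        for iv in regions
    )
    counts = np.array([tags.count_overlapping(iv) for iv in regions], dtype=float)
    return SignalVector(ids, counts * RP10M_SCALE / library_size, library_size)


def profile_matrix(
    anchors: list[tuple[str, int]],
    tags: IntervalSet,
    half_window: int,
    n_bins: int,
    library_size: int | None = None,
) -> np.ndarray:
    """Anchors x bins RP10M matrix over symmetric windows.

    ``anchors`` are (chrom, position) pairs; the window is
    ``[pos - half_window, pos + half_window)`` split into ``n_bins`` equal
    bins. Column means give the averaged signal profile around the anchor
    class (e.g. ATAC or H3K4me1 signal around regions acquiring H3K27ac).
    """
    if n_bins <= 0 or (2 * half_window) % n_bins != 0:
        raise BinningError(f"{n_bins} bins do not evenly divide a {2 * half_window} bp window")
    if library_size is None:
        library_size = len(tags)
    if library_size <= 0:
        raise EmptyLibrary("library_size must be > 0")
    bin_width = (2 * half_window) // n_bins
    scale = RP10M_SCALE / library_size
    out = np.zeros((len(anchors), n_bins), dtype=float)
    for i, (chrom, pos) in enumerate(anchors):
        left = pos - half_window
        window = GenomicInterval(chrom, max(0, left), pos + half_window)
        for tag in tags.overlapping(window):
            j = (tag.midpoint - left) // bin_width
            if 0 <= j < n_bins:
                out[i, j] += scale
    return out
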