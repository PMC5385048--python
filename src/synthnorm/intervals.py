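"""Genomic coordinate model and fixed-width binning.

Coordinates are 0-based, half-open everywhere in memory (BED native).  A
:class:`BinGrid` tiles each chromosome with non-overlapping fixed-width bins;
it is the coordinate backbone shared by coverage profiles, ratio tracks and
segmentation.  Trailing partial bins are kept in the grid so tiling is exact,
but flagged unusable so ratio/MSSD/segmentation computations skip them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

_CHROM_NUM = re.compile(r"^(chr)?(\d+|[XYxy])$")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving chr1..chr22, chrX, chrY order; other names last, lexical."""
    m = _CHROM_NUM.match(chrom)
    if m:
        tok = m.group(2).upper()
        if tok.isdigit():
            return (0, int(tok), chrom)
        return (0, 23 if tok == "X" else 24, chrom)
    return (1, 0, chrom)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class AdjacencyClass(Enum):
    """Category of a pair of adjacent bins by on/off-target status."""

    ON_ON = "ON_ON"
    OFF_OFF = "OFF_OFF"
    MIXED = "MIXED"


@dataclass
class BinGrid:
    """Fixed-width partition of a genome into bins.

    Attributes
    ----------
    chrom_lengths : dict
        Chromosome name -> length in bases, in natural sort order.
    bin_width : int
        Nominal bin width in bases.
    chrom_index : ndarray of int
        Per-bin index into ``chroms``.
    starts, ends : ndarray of int
        Per-bin half-open coordinates.
    target_flag : ndarray of bool
        True where the bin overlaps >=1 target interval (set by
        :func:`classify_bins`).
    usable_flag : ndarray of bool
        Full-width bins; partial trailing bins are excluded from analysis.
    """

    chrom_lengths: dict
    bin_width: int
    chrom_index: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    target_flag: np.ndarray
    usable_flag: np.ndarray
    chroms: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous slice of bin indices belonging to ``chrom``."""
        slices = self.__dict__.get("_slices")
        if slices is None:
            # bins are stored in chromosome blocks, so searchsorted suffices
            slices = {
                c: slice(
                    int(np.searchsorted(self.chrom_index, ci, side="left")),
                    int(np.searchsorted(self.chrom_index, ci, side="right")),
                )
                for ci, c in enumerate(self.chroms)
            }
            self.__dict__["_slices"] = slices
        return slices[chrom]

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index containing (chrom, pos); -1 if outside the grid."""
        if chrom not in self.chroms:
            return -1
        if not (0 <= pos < self.chrom_lengths[chrom]):
            return -1
        sl = self.chrom_slice(chrom)
        return sl.start + pos // self.bin_width

    def interval_of(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chroms[int(self.chrom_index[i])], int(self.starts[i]), int(self.ends[i])
        )

    def compatible_with(self, other: "BinGrid") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chroms == other.chroms
            and self.chrom_lengths == other.chrom_lengths
        )


def build_bin_grid(chrom_lengths: dict, bin_width: int) -> BinGrid:
    """Tile each chromosome with fixed-width bins.

    Every bin except possibly the last per chromosome has length ``bin_width``;
    a trailing partial bin is retained (tiling is exact) but marked unusable.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not chrom_lengths:
        raise ValueError("no reference: empty chromosome map")
    for c, ln in chrom_lengths.items():
        if ln <= 0:
            raise ValueError(f"chromosome {c} has non-positive length {ln}")

    chroms = sorted(chrom_lengths, key=natural_chrom_key)
    ordered = {c: int(chrom_lengths[c]) for c in chroms}
    ci_parts, start_parts, end_parts, usable_parts = [], [], [], []
    for ci, c in enumerate(chroms):
        ln = ordered[c]
        starts = np.arange(0, ln, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, ln)
        ci_parts.append(np.full(len(starts), ci, dtype=np.int32))
        start_parts.append(starts)
        end_parts.append(ends)
        usable_parts.append((ends - starts) == bin_width)
    starts = np.concatenate(start_parts)
    return BinGrid(
        chrom_lengths=ordered,
        bin_width=int(bin_width),
        chrom_index=np.concatenate(ci_parts),
        starts=starts,
        ends=np.concatenate(end_parts),
        target_flag=np.zeros(len(starts), dtype=bool),
        usable_flag=np.concatenate(usable_parts),
        chroms=chroms,
    )


def classify_bins(grid: BinGrid, targets: list) -> BinGrid:
    """Set ``target_flag`` from capture-target intervals.

    A bin is on-target on any >=1 bp overlap with a target.  Targets on
    chromosomes absent from the grid are skipped with a logged count.
    """
    flag = np.zeros(grid.n_bins, dtype=bool)
    skipped = 0
    for t in targets:
        if t.chrom not in grid.chroms:
            skipped += 1
            continue
        sl = grid.chrom_slice(t.chrom)
        ln = grid.chrom_lengths[t.chrom]
        first = min(t.start, ln - 1) // grid.bin_width
        last = (min(t.end, ln) - 1) // grid.bin_width
        n_chrom = sl.stop - sl.start
        first = min(first, n_chrom - 1)
        last = min(last, n_chrom - 1)
        flag[sl.start + first : sl.start + last + 1] = True
    if skipped:
        logger.warning("classify_bins: %d target(s) on unknown chromosomes skipped", skipped)
    grid.target_flag = flag
    return grid


def adjacency_classes(grid: BinGrid) -> list:
    """Classify each within-chromosome pair of adjacent usable bins.

    Returns a list of ``(i, i+1, AdjacencyClass)`` using global bin indices.
    Pairs never span chromosomes and never include unusable bins.
    """
    out = []
    same_chrom = grid.chrom_index[:-1] == grid.chrom_index[1:]
    both_usable = grid.usable_flag[:-1] & grid.usable_flag[1:]
    for i in np.nonzero(same_chrom & both_usable)[0]:
        a, b = grid.target_flag[i], grid.target_flag[i + 1]
        if a and b:
            cls = AdjacencyClass.ON_ON
        elif not a and not b:
            cls = AdjacencyClass.OFF_OFF
        else:
            cls = AdjacencyClass.MIXED
        out.append((int(i), int(i) + 1, cls))
    return out
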