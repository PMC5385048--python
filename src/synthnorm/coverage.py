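"""Per-bin coverage profiles, read ratios, and capture-bias diagnostics.

A :class:`CoverageProfile` holds one sample's per-bin read counts on a
:class:`~synthnorm.intervals.BinGrid` plus its library size and fold
enrichment.  Tumor/normal comparison happens on the read ratio (RR) scale:
library-size-normalized count ratios, centred at 1 for balanced diploid
territory.  The ratio difference (RD) between adjacent bins, summarized per
adjacency class, diagnoses capture-induced technical bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import AdjacencyClass, BinGrid

logger = logging.getLogger(__name__)

ROLES = ("tumor", "normal", "synthetic")


@dataclass
class CoverageProfile:
    """One sample's per-bin read counts aligned to a bin grid."""

    sample_id: str
    role: str
    counts: np.ndarray
    library_size: float
    grid: BinGrid
    fold_enrichment: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if len(self.counts) != self.grid.n_bins:
            raise ValueError(
                f"counts length {len(self.counts)} != grid bins {self.grid.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.library_size < self.counts.sum() - 1e-6:
            raise ValueError("library_size smaller than sum of binned counts")


@dataclass
class RatioTrack:
    """Per-bin tumor/normal read ratios; NaN marks missing bins."""

    rr: np.ndarray
    grid: BinGrid
    adjusted: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rr)


@dataclass
class RdSummary:
    """Ratio differences between adjacent bins, grouped by adjacency class."""

    values: dict  # AdjacencyClass -> ndarray of RD values
    mean: dict
    variance: dict


def count_reads(alignment_source, grid: BinGrid, mapq_min: int = 1) -> CoverageProfile:
    """Count primary, non-duplicate, MAPQ-filtered reads per bin.

    Each passing read is assigned to exactly one bin by its leftmost aligned
    base.  ``library_size`` is the number of passing reads genome-wide,
    including reads on contigs outside the grid.

    Parameters
    ----------
    alignment_source : str or pysam.AlignmentFile
        SAM/BAM path or an open alignment file.
    """
    import pysam

    close = False
    if isinstance(alignment_source, (str, bytes)):
        alignment_source = pysam.AlignmentFile(str(alignment_source))
        close = True
    counts = np.zeros(grid.n_bins, dtype=float)
    library_size = 0
    try:
        sample_id = alignment_source.filename.decode() if alignment_source.filename else "sample"
        for read in alignment_source.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < mapq_min
            ):
                continue
            library_size += 1
            i = grid.bin_of(read.reference_name, read.reference_start)
            if i >= 0:
                counts[i] += 1
    finally:
        if close:
            alignment_source.close()
    if library_size == 0:
        logger.warning("count_reads: no mapped reads passed filters; all-zero profile")
    return CoverageProfile(
        sample_id=sample_id, role="normal", counts=counts,
        library_size=float(library_size), grid=grid,
    )


def fold_enrichment_from_reads(
    on_target_reads: float, total_reads: float, target_bp: float, genome_bp: float
) -> float:
    """Ratio-of-fractions fold enrichment.

    (on-target reads / total reads) / (target bases / genome bases): the fold
    change by which capture amplifies the target territory above uniform
    genomic background.
    """
    if total_reads <= 0:
        raise ValueError("zero total reads")
    if target_bp <= 0 or genome_bp <= 0:
        raise ValueError("territory must be positive")
    return (on_target_reads / total_reads) / (target_bp / genome_bp)


def fold_enrichment(profile: CoverageProfile, genome_length: float | None = None) -> float:
    """Fold enrichment of a profile at bin resolution.

    On-target reads are approximated by the counts in target-flagged bins and
    the target territory by the total bases of those bins.  Callers with exact
    read-level numbers should use :func:`fold_enrichment_from_reads`.
    """
    grid = profile.grid
    if genome_length is None:
        genome_length = float(sum(grid.chrom_lengths.values()))
    tgt = grid.target_flag
    target_bp = float((grid.ends[tgt] - grid.starts[tgt]).sum())
    on_target = float(profile.counts[tgt].sum())
    total = float(profile.counts.sum())
    return fold_enrichment_from_reads(on_target, total, target_bp, genome_length)


def read_ratio(
    tumor: CoverageProfile, normal: CoverageProfile, min_normal_count: float = 20
) -> RatioTrack:
    """Library-size-normalized tumor/normal read ratio per bin.

    rr[i] = (t_i / T) / (n_i / N).  Bins that are unusable (partial width) or
    whose normal count is below ``min_normal_count`` are missing (NaN).
    """
    if not tumor.grid.compatible_with(normal.grid):
        raise ValueError("tumor and normal profiles are on different grids")
    if min_normal_count < 1:
        raise ValueError("min_normal_count must be >= 1")
    T, N = tumor.library_size, normal.library_size
    if T <= 0 or N <= 0:
        raise ValueError("library sizes must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (tumor.counts / T) / (normal.counts / N)
    bad = (~tumor.grid.usable_flag) | (normal.counts < min_normal_count)
    rr = np.where(bad, np.nan, rr)
    return RatioTrack(
        rr=rr, grid=tumor.grid,
        meta={"tumor": tumor.sample_id, "normal": normal.sample_id},
    )


def rd_summary(track: RatioTrack, classes: list) -> RdSummary:
    """Adjacent-bin ratio differences, per adjacency class.

    RD for the pair (i, i+1) is rr[i+1] - rr[i]; pairs with a missing member
    are skipped.
    """
    values = {c: [] for c in AdjacencyClass}
    rr = track.rr
    for i, j, cls in classes:
        if np.isnan(rr[i]) or np.isnan(rr[j]):
            continue
        values[cls].append(rr[j] - rr[i])
    if not any(values[c] for c in AdjacencyClass):
        logger.warning("rd_summary: no valid adjacent pairs")
    arrays = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    mean = {c: (float(a.mean()) if len(a) else np.nan) for c, a in arrays.items()}
    var = {c: (float(a.var()) if len(a) else np.nan) for c, a in arrays.items()}
    return RdSummary(values=arrays, mean=mean, variance=var)


def metric_regression(rd_means: pd.Series, metric_diffs: pd.DataFrame) -> pd.DataFrame:
    """OLS of per-sample mean RD against each quality-metric difference.

    ``metric_diffs`` holds tumor-minus-normal differences of externally
    computed quality metrics, one row per sample.  Returns one row per metric
    with slope, intercept, r_squared, and a ``constant_predictor`` flag
    (R^2 reported as 0 for degenerate predictors).
    """
    common = rd_means.index.intersection(metric_diffs.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples for regression")
    y = rd_means.loc[common].to_numpy(dtype=float)
    rows = []
    for col in metric_diffs.columns:
        x = metric_diffs.loc[common, col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((col, 0.0, float(y.mean()), 0.0, True))
            continue
        res = stats.linregress(x, y)
        rows.append((col, res.slope, res.intercept, res.rvalue**2, False))
    return pd.DataFrame(
        rows, columns=["metric", "slope", "intercept", "r_squared", "constant_predictor"]
    ).set_index("metric")
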