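"""Segment-level accuracy statistics and cohort summaries.

Calls and truth are compared as base-length interval sets inside an
evaluable *space* (by default the union of usable bins, not the whole
genome, so unassayed territory cannot inflate specificity):

* Jaccard index  = |calls ∩ truth| / |calls ∪ truth|
* sensitivity    = |calls ∩ truth| / |truth|
* specificity    = |space \\ (calls ∪ truth)| / |space \\ truth|

Gene-level concordance between two discrete {-1, 0, +1} call matrices uses
a per-gene paired Wilcoxon signed-rank test with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import BinGrid, GenomicInterval


def merge_intervals(intervals) -> list:
    """Sorted, disjoint union of a list of intervals."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(a, b) -> list:
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    by_chrom_b = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iva in a:
        for ivb in by_chrom_b.get(iva.chrom, ()):
            s, e = max(iva.start, ivb.start), min(iva.end, ivb.end)
            if s < e:
                out.append(GenomicInterval(iva.chrom, s, e))
    return merge_intervals(out) if out else []

def subtract_intervals(a, b) -> list:
    """Merged a minus merged b."""
    a = merge_intervals(a)
    by_chrom_b = {}
    for iv in merge_intervals(b):
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out = []
    for iva in a:
        pos = iva.start
        for ivb in by_chrom_b.get(iva.chrom, ()):
            if ivb.end <= pos or ivb.start >= iva.end:
                continue
            if ivb.start > pos:
                out.append(GenomicInterval(iva.chrom, pos, ivb.start))
            pos = max(pos, ivb.end)
            if pos >= iva.end:
                break
        if pos < iva.end:
            out.append(GenomicInterval(iva.chrom, pos, iva.end))
    return out


def total_length(intervals) -> int:
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0


@dataclass
class EvalResult:
    sample_id: str
    jaccard: float
    sensitivity: float
    specificity: float
    evaluated_space: int


def overlap_stats(calls, truth, space, sample_id: str = "sample") -> EvalResult:
    """Base-length Jaccard, sensitivity, specificity of calls vs truth.

    All intervals must lie within ``space``.  Empty-set conventions: JI is 1
    when both sets are empty, sensitivity 1 when truth is empty, specificity
    1 when truth covers the whole space.
    """
    if not space:
        raise ValueError("space must be non-empty")
    space = merge_intervals(space)
    for name, ivs in (("calls", calls), ("truth", truth)):
        if ivs and subtract_intervals(ivs, space):
            raise ValueError(f"{name} intervals extend outside the evaluable space")
    inter = total_length(intersect_intervals(calls, truth)) if (calls and truth) else 0
    union = total_length(list(calls) + list(truth)) if (calls or truth) else 0
    truth_len = total_length(truth)
    space_len = total_length(space)
    not_called = total_length(subtract_intervals(space, list(calls) + list(truth)))
    not_truth = space_len - truth_len
    return EvalResult(
        sample_id=sample_id,
        jaccard=inter / union if union else 1.0,
        sensitivity=inter / truth_len if truth_len else 1.0,
        specificity=not_called / not_truth if not_truth else 1.0,
        evaluated_space=space_len,
    )


def altered_intervals(calls, direction: int | None = None) -> list:
    """Intervals of segments with non-zero (or the given) direction."""
    if direction is None:
        ivs = [c.segment.interval for c in calls if c.direction != 0]
    else:
        ivs = [c.segment.interval for c in calls if c.direction == direction]
    return merge_intervals(ivs) if ivs else []


def direction_aware_stats(calls, truth, space, sample_id: str = "sample") -> dict:
    """Overlap statistics computed separately for gain and loss territory."""
    out = {}
    for name, d in (("gain", 1), ("loss", -1)):
        out[name] = overlap_stats(
            altered_intervals(calls, d), altered_intervals(truth, d), space, sample_id
        )
    return out


def gene_concordance(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, fdr: float = 0.05):
    """Per-gene paired Wilcoxon test between two discrete call matrices.

    Returns ``(table, discordant_genes)`` where the table has per-gene p and
    BH-adjusted q values.  Genes whose paired differences are all zero get
    p = 1.  The test is two-sided (symmetric under matrix exchange).
    """
    if not matrix_a.index.equals(matrix_b.index) or not matrix_a.columns.equals(
        matrix_b.columns
    ):
        raise ValueError("matrices must share genes and samples")
    if matrix_a.shape[1] < 6:
        raise ValueError("need >= 6 samples for a meaningful paired test")
    pvals = np.ones(len(matrix_a.index))
    for i, gene in enumerate(matrix_a.index):
        d = matrix_a.loc[gene].to_numpy(dtype=float) - matrix_b.loc[gene].to_numpy(dtype=float)
        if np.all(d == 0):
            continue
        res = stats.wilcoxon(
            d, zero_method="wilcox", correction=True, method="auto", alternative="two-sided"
        )
        pvals[i] = res.pvalue
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    table = pd.DataFrame(
        {"p": pvals, "q": qvals, "discordant": reject}, index=matrix_a.index
    )
    return table, list(matrix_a.index[reject])


def percent_overlap(concordance_table: pd.DataFrame) -> float:
    """Percent of genes whose discrete calls do not differ significantly."""
    return 100.0 * float((~concordance_table["discordant"]).mean())


@dataclass
class FrequencyLandscape:
    gain_freq: np.ndarray
    loss_freq: np.ndarray
    grid: BinGrid

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        return pd.DataFrame(
            {
                "chrom": [g.chroms[i] for i in g.chrom_index],
                "start": g.starts,
                "end": g.ends,
                "gain_freq": self.gain_freq,
                "loss_freq": self.loss_freq,
            }
        )


def frequency_landscape(cohort_calls: list, grid: BinGrid) -> FrequencyLandscape:
    """Per-bin fraction of samples called gained / lost across a cohort.

    Bins not covered by any segment in a sample contribute neither gain nor
    loss for that sample (0/0 territory reports frequency 0).
    """
    if not cohort_calls:
        raise ValueError("need >= 1 sample")
    gain = np.zeros(grid.n_bins)
    loss = np.zeros(grid.n_bins)
    for calls in cohort_calls:
        for c in calls:
            if c.direction == 1:
                gain[c.segment.bin_indices] += 1
            elif c.direction == -1:
                loss[c.segment.bin_indices] += 1
    n = len(cohort_calls)
    return FrequencyLandscape(gain_freq=gain / n, loss_freq=loss / n, grid=grid)
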