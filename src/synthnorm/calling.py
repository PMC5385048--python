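"""Integer copy number, discrete gain/loss calls, and tumor purity.

Each segment's mean log2 ratio is modelled as a normal mixture whose
component means are pinned by the purity-dilution formula

    log2( (p * c + 2 * (1 - p)) / 2 )

for integer copy number c and purity p: a tumor segment at copy number c in
a specimen that is a fraction p tumor cells appears diluted toward the
diploid ratio.  Purity is estimated by a grid search: at each candidate
purity the mixture (shared variance estimated from the data, an
exponentially decaying prior centred on c = 2) is scored by the
bin-count-weighted log marginal likelihood of the segment means.  The decay
prior resolves the inherent purity/ploidy confounding (e.g. p = 1 with
c in {2, 3} fits exactly as well as p = 0.5 with c in {2, 4}) toward the
higher-purity / lower-ploidy solution.

Heuristic filters then dissolve weakly supported copy levels (too few
segments, or a median-MAF separation from a neighbouring level below a
minimum gap), and discrete direction calls apply fixed log2 thresholds
(gains > 0.25, losses < -0.32).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cbs import LOG2_EPS, Segment, SegmentSet

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    gain_log2: float = 0.25
    loss_log2: float = -0.32
    min_segments_per_level: int = 2
    min_maf_gap: float = 0.05
    max_cn: int = 8
    purity_min: float = 0.05
    purity_max: float = 1.0
    purity_step: float = 0.01
    prior_decay: float = 1.0  # log-prior penalty per unit |c - 2|
    sigma_floor: float = 0.02

    def __post_init__(self):
        if not (self.loss_log2 < 0 < self.gain_log2):
            raise ValueError("need loss_log2 < 0 < gain_log2")
        if not (0 < self.purity_min <= self.purity_max <= 1):
            raise ValueError("invalid purity grid")


@dataclass
class SegmentCall:
    segment: Segment
    integer_cn: int
    posterior: float
    direction: int  # -1, 0, +1
    median_maf: float = float("nan")


@dataclass
class PuritySolution:
    purity: float
    candidate_grid: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    flag: str = ""


def expected_log2(cn, purity: float):
    """Expected log2 ratio of copy number ``cn`` at the given purity."""
    if purity <= 0 or purity > 1:
        raise ValueError("purity must be in (0, 1]")
    cn = np.asarray(cn, dtype=float)
    if np.any(cn < 0):
        raise ValueError("cn must be >= 0")
    arg = np.maximum((purity * cn + 2.0 * (1.0 - purity)) / 2.0, LOG2_EPS)
    out = np.log2(arg)
    return float(out) if out.ndim == 0 else out


def _log_prior(max_cn: int, decay: float) -> np.ndarray:
    c = np.arange(max_cn + 1)
    lp = -decay * np.abs(c - 2.0)
    return lp - logsumexp(lp)


def direction_of(mean_log2: float, config: CallerConfig) -> int:
    if mean_log2 > config.gain_log2:
        return 1
    if mean_log2 < config.loss_log2:
        return -1
    return 0


def _score_purity(y, w, purity, config):
    """Score one purity; returns (score, sigma, assignments)."""
    mu = expected_log2(np.arange(config.max_cn + 1), purity)
    d = y[:, None] - mu[None, :]
    nearest = np.argmin(np.abs(d), axis=1)
    resid = d[np.arange(len(y)), nearest]
    sigma = max(float(np.sqrt(np.average(resid**2, weights=w))), config.sigma_floor)
    lp = _log_prior(config.max_cn, config.prior_decay)
    ll = lp[None, :] - 0.5 * (d / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    score = float(np.sum(w * logsumexp(ll, axis=1)))
    return score, sigma, ll


def fit_integer_cn(
    segments: SegmentSet, maf_by_segment=None, config: CallerConfig | None = None
):
    """Assign integer copy numbers to segments and estimate purity.

    Parameters
    ----------
    maf_by_segment : array-like or None
        Per-segment median MAF (NaN where unavailable), used by the
        level-separation filter.

    Returns ``(calls, purity_solution)``.
    """
    config = config or CallerConfig()
    segs = segments.segments
    if not segs:
        raise ValueError("no segments to call")
    y = np.array([s.mean_log2 for s in segs])
    w = np.array([s.n_bins for s in segs], dtype=float)
    maf = (
        np.asarray(maf_by_segment, dtype=float)
        if maf_by_segment is not None
        else np.full(len(segs), np.nan)
    )

    # Degenerate cohort: a genome with no ratio contrast says nothing about purity.
    if np.ptp(y) < config.sigma_floor:
        calls = [
            SegmentCall(s, 2, 1.0, direction_of(s.mean_log2, config), m)
            for s, m in zip(segs, maf)
        ]
        grid = pd.DataFrame({"purity": [1.0], "score": [0.0]})
        return calls, PuritySolution(
            purity=1.0, candidate_grid=grid, flag="unidentifiable",
            diagnostics={"level_counts": {2: len(segs)}},
        )

    purities = np.round(
        np.arange(config.purity_min, config.purity_max + 1e-9, config.purity_step), 10
    )
    scores = np.empty(len(purities))
    for i, p in enumerate(purities):
        scores[i], _, _ = _score_purity(y, w, p, config)
    best_i = int(np.argmax(scores))  # first max: lower purity only on exact tie
    # prefer the highest purity among score ties (lower-ploidy explanation)
    ties = np.nonzero(scores >= scores[best_i] - 1e-9)[0]
    best_i = int(ties[-1]) if len(ties) else best_i
    purity = float(purities[best_i])
    _, sigma, ll = _score_purity(y, w, purity, config)

    log_post = ll - logsumexp(ll, axis=1, keepdims=True)
    post = np.exp(log_post)
    cn = np.empty(len(segs), dtype=int)
    for s_i in range(len(segs)):
        order = sorted(
            range(config.max_cn + 1),
            key=lambda c: (-post[s_i, c], abs(c - 2), c),  # ties toward cn near 2
        )
        cn[s_i] = order[0]

    mu = expected_log2(np.arange(config.max_cn + 1), purity)
    cn = _apply_filters(cn, y, maf, mu, config)

    calls = [
        SegmentCall(
            segment=s, integer_cn=int(cn[i]), posterior=float(post[i, cn[i]]),
            direction=direction_of(s.mean_log2, config), median_maf=float(maf[i]),
        )
        for i, s in enumerate(segs)
    ]
    level_counts = {int(c): int(np.sum(cn == c)) for c in np.unique(cn)}
    solution = PuritySolution(
        purity=purity,
        candidate_grid=pd.DataFrame({"purity": purities, "score": scores}),
        diagnostics={"sigma": sigma, "level_counts": level_counts},
    )
    return calls, solution


def _apply_filters(cn, y, maf, mu, config):
    """Dissolve weakly supported copy levels into the nearest surviving level."""
    cn = cn.copy()

    def reassign(dissolved: set):
        surviving = sorted(set(cn) - dissolved)
        if not surviving:
            return
        for i in np.nonzero(np.isin(cn, list(dissolved)))[0]:
            cn[i] = min(surviving, key=lambda c: (abs(y[i] - mu[c]), abs(c - 2)))

    # minimum segments per level
    counts = {c: int(np.sum(cn == c)) for c in set(cn)}
    weak = {c for c, n in counts.items() if n < config.min_segments_per_level}
    if weak and weak != set(counts):
        reassign(weak)

    # minimum MAF separation between consecutive surviving levels
    if np.isfinite(maf).any() and config.min_maf_gap > 0:
        while True:
            levels = sorted(set(cn))
            med = {
                c: np.nanmedian(maf[cn == c]) if np.isfinite(maf[cn == c]).any() else np.nan
                for c in levels
            }
            dissolved = None
            for a, b in zip(levels[:-1], levels[1:]):
                if np.isnan(med[a]) or np.isnan(med[b]):
                    continue
                if abs(med[a] - med[b]) < config.min_maf_gap:
                    pair = [c for c in (a, b) if c != 2]
                    if not pair:
                        continue
                    dissolved = min(pair, key=lambda c: (np.sum(cn == c), -abs(c - 2)))
                    break
            if dissolved is None or len(set(cn)) == 1:
                break
            reassign({dissolved})
    return cn


def segment_median_maf(segments: SegmentSet, maf_track) -> np.ndarray:
    """Median MAF per segment over its member bins (NaN when none defined)."""
    out = np.full(len(segments.segments), np.nan)
    for i, s in enumerate(segments.segments):
        vals = maf_track.maf[s.bin_indices]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[i] = np.median(vals)
    return out


def discrete_gene_matrix(calls_by_sample: dict, genes: list) -> pd.DataFrame:
    """Genes x samples matrix of discrete calls in {-1, 0, +1}.

    Each gene takes the direction of the segment with the largest overlap;
    genes overlapping no segment are 0.  ``genes`` is a list of
    ``(name, GenomicInterval)``; duplicate names are an error.
    """
    names = [n for n, _ in genes]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names: {dup}")
    samples = list(calls_by_sample)
    mat = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    for sample, calls in calls_by_sample.items():
        for name, g in genes:
            best_len, best_dir = 0, 0
            for c in calls:
                iv = c.segment.interval
                if iv.chrom != g.chrom:
                    continue
                ov = min(iv.end, g.end) - max(iv.start, g.start)
                if ov > best_len:
                    best_len, best_dir = ov, c.direction
            mat.loc[name, sample] = best_dir
    return mat
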