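"""Diploid anchoring of the read-ratio track.

Aneuploid tumors break the assumption that the average ratio is diploid, so
the track is re-anchored using allelic balance: bins whose median minor
allele fraction (MAF) exceeds a threshold (default 0.45) are candidate
copy-neutral territory.  A Gaussian mixture is fitted to the candidate read
ratios with BIC model selection; the component with the smallest mean is
taken as diploid (balanced higher-ploidy states sit at higher ratios), and
all ratios are rescaled so that component's mean is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .coverage import RatioTrack
from .intervals import BinGrid

logger = logging.getLogger(__name__)


@dataclass
class MafTrack:
    """Per-bin median minor allele fraction; NaN where no informative site."""

    maf: np.ndarray
    n_sites: np.ndarray
    grid: BinGrid


def maf_track(sites: pd.DataFrame, grid: BinGrid, min_depth: int = 10) -> MafTrack:
    """Median per-bin minor allele fraction from a per-site allele-count table.

    Sites with depth < ``min_depth`` or with either allele unobserved
    (homozygous-looking) are excluded.  Site MAF = min(ref, alt) / depth.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    maf = np.full(grid.n_bins, np.nan)
    n_sites = np.zeros(grid.n_bins, dtype=int)
    if len(sites) == 0:
        return MafTrack(maf=maf, n_sites=n_sites, grid=grid)
    ref = sites["ref_count"].to_numpy(dtype=float)
    alt = sites["alt_count"].to_numpy(dtype=float)
    depth = ref + alt
    keep = (depth >= min_depth) & (ref > 0) & (alt > 0)
    site_maf = np.minimum(ref, alt)[keep] / depth[keep]
    bins = np.array(
        [grid.bin_of(c, int(p)) for c, p in zip(sites["chrom"][keep], sites["pos"][keep])]
    )
    ok = bins >= 0
    bins, site_maf = bins[ok], site_maf[ok]
    order = np.argsort(bins, kind="stable")
    bins, site_maf = bins[order], site_maf[order]
    uniq, starts_idx = np.unique(bins, return_index=True)
    for b, s, e in zip(uniq, starts_idx, np.append(starts_idx[1:], len(bins))):
        maf[b] = np.median(site_maf[s:e])
        n_sites[b] = e - s
    return MafTrack(maf=maf, n_sites=n_sites, grid=grid)


@dataclass
class DiploidAnchor:
    n_components: int
    component_means: np.ndarray
    component_weights: np.ndarray
    diploid_component: int
    scale_factor: float
    bic_table: dict = field(default_factory=dict)
    used_fallback: bool = False


def fit_diploid_anchor(
    track: RatioTrack,
    maf: MafTrack | None,
    maf_threshold: float = 0.45,
    max_components: int = 5,
    seed: int = 0,
    min_candidates: int = 30,
    min_diploid_weight: float = 0.05,
) -> DiploidAnchor:
    """Fit a GMM to candidate copy-neutral read ratios and pick the diploid level.

    Candidates are defined bins with median MAF strictly greater than
    ``maf_threshold``.  Mixtures with 1..``max_components`` components are
    fitted by EM (10 k-means++ restarts, tol 1e-6, max 500 iterations) and the
    minimal-BIC model kept.  The smallest-mean component is declared diploid
    and ``scale_factor`` makes its mean exactly 1.

    The diploid pick ignores components with weight below
    ``min_diploid_weight``: homozygously deleted territory is allelically
    silent (its residual reads come from contaminating normal cells, so its
    median MAF sits near 0.5) and can slip into the candidate set, but being
    focal it can only ever form a minor component, never the diploid bulk.

    Falls back to the whole defined track, with a logged warning, when fewer
    than ``min_candidates`` candidate bins exist or no MAF data are supplied.
    """
    if track.adjusted:
        raise ValueError("track is already adjusted")
    defined = track.defined
    used_fallback = False
    if maf is not None:
        cand = defined & (maf.maf > maf_threshold)
    else:
        cand = np.zeros_like(defined)
    if cand.sum() < min_candidates:
        logger.warning(
            "fit_diploid_anchor: %d candidate bins < %d; falling back to all defined bins",
            int(cand.sum()), min_candidates,
        )
        cand = defined
        used_fallback = True
    x = track.rr[cand].reshape(-1, 1)
    if len(x) < 2:
        raise ValueError("not enough defined bins to fit an anchor")
    if np.ptp(x) == 0:  # constant data: single degenerate component
        mean = float(x[0, 0])
        return DiploidAnchor(
            n_components=1, component_means=np.array([mean]),
            component_weights=np.array([1.0]), diploid_component=0,
            scale_factor=1.0 / mean, bic_table={1: float("nan")},
            used_fallback=used_fallback,
        )
    best, bic_table = None, {}
    for k in range(1, max_components + 1):
        if k > len(x):
            break
        gm = GaussianMixture(
            n_components=k, n_init=10, init_params="k-means++",
            tol=1e-6, max_iter=500, random_state=seed, reg_covar=1e-10,
        ).fit(x)
        bic = gm.bic(x)
        bic_table[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    eligible = np.nonzero(weights >= min_diploid_weight)[0]
    if len(eligible) == 0:
        eligible = np.arange(len(means))
    diploid = int(eligible[np.argmin(means[eligible])])
    return DiploidAnchor(
        n_components=gm.n_components,
        component_means=means,
        component_weights=gm.weights_.ravel(),
        diploid_component=diploid,
        scale_factor=float(1.0 / means[diploid]),
        bic_table=bic_table,
        used_fallback=used_fallback,
    )


def apply_anchor(track: RatioTrack, anchor: DiploidAnchor) -> RatioTrack:
    """Rescale the track so diploid territory has expected ratio 1."""
    if track.adjusted:
        raise ValueError("already adjusted")
    return RatioTrack(
        rr=track.rr * anchor.scale_factor,
        grid=track.grid,
        adjusted=True,
        meta={**track.meta, "scale_factor": anchor.scale_factor},
    )
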