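"""Circular binary segmentation of the log2 read-ratio track.

Each chromosome (and recursively each piece) is treated as a circle; the arc
maximizing a two-sample t-like statistic between the arc and its complement
is the candidate change-point pair, accepted when its within-piece
permutation p-value is at most ``alpha``.  Segmentation runs on
log2(adjusted rr) so downstream gain/loss thresholds live in log2 space.

The arc statistic for arc (i, j) (bins i..j-1 against the rest) is
``(m1 - m2) / sqrt(s_p^2 (1/k + 1/(n-k)))`` with pooled variance ``s_p^2``
floored at 1e-12 (the floor is part of the statistic's definition; it makes
noiseless steps produce large finite values).  An arc and its circular
complement describe the same split and tie structurally, so the argmax is
defined as the lexicographically smallest (i, j) among arcs within a
relative tolerance (1e-9) of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import RatioTrack
from .intervals import GenomicInterval

LOG2_EPS = 1e-6
_SP2_FLOOR = 1e-12
_TIE_RTOL = 1e-9


def _lex_argmax(T: np.ndarray):
    """Smallest (i, j) among entries within relative tolerance of the max."""
    m = float(np.max(T))
    cand = np.argwhere(T >= m - _TIE_RTOL * max(1.0, abs(m)))
    i, j = cand[0]  # argwhere is row-major sorted
    return int(i), int(j), m


@dataclass
class Segment:
    interval: GenomicInterval
    n_bins: int
    mean_log2: float
    p_value: float
    bin_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SegmentSet:
    sample_id: str
    segments: list
    params: dict = field(default_factory=dict)


def _stat_matrix(x: np.ndarray):
    """|T| over all arcs (i, j), 0 <= i < j <= n, as an (n+1, n+1) matrix."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    tot, totq = S[-1], Q[-1]
    idx = np.arange(n + 1, dtype=float)
    k = idx[None, :] - idx[:, None]
    s = S[None, :] - S[:, None]
    q = Q[None, :] - Q[:, None]
    valid = (k >= 1) & (k <= n - 1)
    k = np.where(valid, k, 1.0)
    comp = np.where(valid, n - k, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s / k
        m2 = (tot - s) / comp
        within = (q - s * s / k) + ((totq - q) - (tot - s) ** 2 / comp)
        sp2 = np.maximum(within / max(n - 2, 1), _SP2_FLOOR)
        T = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / k + 1.0 / comp))
    T[~valid] = -np.inf
    return T, valid


def max_arc_statistic(x) -> tuple:
    """Best circular arc (i, j) and its |T| statistic.

    Returns ``(i, j, statistic)`` where the arc covers bins i..j-1.  For a
    constant series the statistic is 0 with arc (0, 1).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        return 0, 1, 0.0
    T, _ = _stat_matrix(x)
    return _lex_argmax(T)


def _masked_max(x: np.ndarray, mask: np.ndarray):
    T, _ = _stat_matrix(x)
    return _lex_argmax(np.where(mask, T, -np.inf))


def _split_mask(n: int, min_width: int) -> np.ndarray:
    """Arcs whose induced linear pieces all have >= min_width bins."""
    idx = np.arange(n + 1)
    i = idx[:, None]
    j = idx[None, :]
    k = j - i
    ok = (k >= 1) & (k <= n - 1)
    ok &= k >= min_width
    ok &= (n - k) >= min_width
    ok &= (i == 0) | (i >= min_width)
    ok &= (j == n) | ((n - j) >= min_width)
    return ok


def _perm_pvalue(x, mask, observed, alpha, n_permutations, rng):
    """Permutation p-value of the observed max statistic, with early stop.

    Stops as soon as the exceedance count guarantees p > alpha (the split
    will be rejected regardless of the remaining permutations).
    """
    threshold = int(np.floor(alpha * n_permutations))
    exceed = 0
    for b in range(n_permutations):
        xp = rng.permutation(x)
        T, _ = _stat_matrix(xp)
        m = np.max(np.where(mask, T, -np.inf))
        if m >= observed:
            exceed += 1
            if exceed > threshold:
                return exceed / (b + 1)  # early reject; p > alpha
    return exceed / n_permutations


def segment(
    track: RatioTrack,
    alpha: float = 0.01,
    n_permutations: int = 10000,
    min_width: int = 2,
    seed: int = 0,
) -> SegmentSet:
    """Segment the adjusted track into pieces of constant log2 ratio.

    Missing bins are skipped entirely (segments contain only defined usable
    bins; their intervals span from the first to the last member bin).
    Chromosomes with fewer than ``min_width`` defined bins, or fewer than 4,
    yield a single segment with p = 1.
    """
    if not track.adjusted:
        raise ValueError("track must be diploid-anchored before segmentation")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    rng = np.random.default_rng(seed)
    grid = track.grid
    x_all = np.log2(np.maximum(track.rr, LOG2_EPS))
    segments = []

    def emit(idxs: np.ndarray, p: float):
        iv = GenomicInterval(
            grid.chroms[int(grid.chrom_index[idxs[0]])],
            int(grid.starts[idxs[0]]),
            int(grid.ends[idxs[-1]]),
        )
        segments.append(
            Segment(
                interval=iv, n_bins=len(idxs),
                mean_log2=float(np.mean(x_all[idxs])),
                p_value=float(p), bin_indices=idxs.copy(),
            )
        )

    def recurse(idxs: np.ndarray, p_in: float):
        n = len(idxs)
        if n < max(4, 2 * min_width):
            emit(idxs, p_in)
            return
        x = x_all[idxs]
        if np.ptp(x) == 0:
            emit(idxs, p_in)
            return
        mask = _split_mask(n, min_width)
        if not mask.any():
            emit(idxs, p_in)
            return
        i, j, obs = _masked_max(x, mask)
        p = _perm_pvalue(x, mask, obs, alpha, n_permutations, rng)
        if p > alpha:
            emit(idxs, p_in)
            return
        pieces = [piece for piece in (idxs[:i], idxs[i:j], idxs[j:]) if len(piece)]
        for piece in pieces:
            recurse(piece, p)

    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        idxs = np.arange(sl.start, sl.stop)[track.defined[sl]]
        if len(idxs) == 0:
            continue
        recurse(idxs, 1.0)

    segments.sort(key=lambda s: (grid.chroms.index(s.interval.chrom), s.interval.start))
    return SegmentSet(
        sample_id=track.meta.get("tumor", "sample"),
        segments=segments,
        params={"alpha": alpha, "n_permutations": n_permutations,
                "min_width": min_width, "seed": seed},
    )
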