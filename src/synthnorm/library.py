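"""Synthetic-normal construction and selection.

Whole-exome capture efficiency varies strongly between protocols and even
protocol versions, so a tumor compared against a mismatched normal shows
technical ratio noise that mimics copy-number change.  This module replaces
the matched normal with a *synthetic* one:

* normals are clustered by their capture-coverage signature (hierarchical
  clustering of mean-centred, top-variance capture-unit coverage),
* within each cluster a 2-D quantile grid over (library size, fold
  enrichment) is built and the normals in each cell are averaged into one
  synthetic profile,
* for a tumor, the candidate cell per cluster is the one matching the tumor's
  library size and fold enrichment, and the winning synthetic is the one
  minimizing the mean square successive difference (MSSD) of the tumor/normal
  read-ratio track.

The KNN strategy skips the library: it ranks every normal by MSSD against
the tumor and takes the per-bin median of the best ``k``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .coverage import CoverageProfile, RatioTrack, read_ratio
from .intervals import BinGrid

logger = logging.getLogger(__name__)


@dataclass
class MssdScore:
    value: float
    n_pairs: int


def mssd(track: RatioTrack) -> MssdScore:
    """Mean square successive difference of the read-ratio track.

    Sum over within-chromosome successive defined-bin pairs of
    (rr[i+1] - rr[i])^2, divided by the number of pairs.  A missing bin
    breaks the chain: no pair is formed across a gap or across chromosomes.
    """
    rr = track.rr
    ok = track.defined
    same_chrom = track.grid.chrom_index[:-1] == track.grid.chrom_index[1:]
    pair = ok[:-1] & ok[1:] & same_chrom
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        raise ValueError("insufficient bins: no successive defined pairs")
    d = rr[1:][pair] - rr[:-1][pair]
    return MssdScore(value=float(np.sum(d * d) / n_pairs), n_pairs=n_pairs)


@dataclass
class ExonCoverageMatrix:
    """Mean-centred normalized coverage of the most variable capture units.

    Rows are normal samples; columns are capture units.  When built from
    per-bin profiles the capture units are the on-target usable bins (the
    capture signature at grid resolution); per-exon matrices computed
    externally can be supplied directly to :func:`cluster_normals`.
    """

    values: np.ndarray  # samples x units, mean-centred per unit
    sample_ids: list
    unit_indices: np.ndarray
    top_variance_k: int


def exon_coverage_matrix(
    normals: list, grid: BinGrid, top_variance_k: int = 2500
) -> ExonCoverageMatrix:
    """Build the clustering matrix from on-target bin coverage.

    Coverage is library-size-normalized, the ``top_variance_k`` highest
    variance units are retained (bounded by availability), and each retained
    column is mean-centred.
    """
    cols = np.nonzero(grid.target_flag & grid.usable_flag)[0]
    if len(cols) == 0:
        raise ValueError("grid has no usable on-target bins")
    X = np.stack([p.counts[cols] / p.library_size for p in normals])
    var = X.var(axis=0)
    k = min(top_variance_k, len(cols))
    # stable top-k: sort by (-variance, column index)
    order = np.lexsort((np.arange(len(cols)), -var))[:k]
    order = np.sort(order)
    Xk = X[:, order]
    Xk = Xk - Xk.mean(axis=0, keepdims=True)
    return ExonCoverageMatrix(
        values=Xk,
        sample_ids=[p.sample_id for p in normals],
        unit_indices=cols[order],
        top_variance_k=k,
    )


def cluster_normals(
    matrix: ExonCoverageMatrix, n_clusters: int, method: str = "complete"
) -> np.ndarray:
    """Agglomerative hierarchical clustering of the coverage matrix.

    Euclidean distance, complete linkage by default; the dendrogram is cut to
    ``n_clusters`` groups.  Returns per-sample labels 0..n_clusters-1,
    relabelled by order of first appearance so the result is deterministic.
    """
    n = len(matrix.sample_ids)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} samples")
    if n_clusters == 1 or n == 1:
        return np.zeros(n, dtype=int)
    Z = scipy_linkage(matrix.values, method=method, metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = np.empty(n, dtype=int)
    seen = {}
    for i, r in enumerate(raw):
        labels[i] = seen.setdefault(r, len(seen))
    return labels


@dataclass
class SyntheticEntry:
    """One synthetic normal: a grid cell of one cluster, with provenance."""

    cluster: int
    cell: tuple
    ls_range: tuple
    fe_range: tuple
    profile: CoverageProfile
    members: list


@dataclass
class NormalLibrary:
    entries: list
    cluster_labels: dict  # sample_id -> cluster
    grid: BinGrid
    scale: tuple = (1.0, 1.0)  # std of (log10 ls, log10 fe) for distance

    def __len__(self):
        return len(self.entries)


def _average_profile(members: list, sample_id: str, grid: BinGrid) -> CoverageProfile:
    """Mean of library-size-normalized counts, rescaled to mean library size."""
    norm = np.stack([p.counts / p.library_size for p in members])
    mean_ls = float(np.mean([p.library_size for p in members]))
    counts = norm.mean(axis=0) * mean_ls
    prof = CoverageProfile(
        sample_id=sample_id, role="synthetic", counts=counts,
        library_size=mean_ls, grid=grid,
    )
    if grid.target_flag.any():
        from .coverage import fold_enrichment

        prof.fold_enrichment = fold_enrichment(prof)
    return prof


def build_library(
    normals: list,
    grid: BinGrid,
    n_clusters: int = 7,
    grid_spec: tuple = (3, 3),
    min_members: int = 3,
    top_variance_k: int = 2500,
    linkage: str = "complete",
) -> NormalLibrary:
    """Cluster normals and average them over a library-size x fold-enrichment grid.

    Per cluster, cell edges are quantiles of the members' library size and
    fold enrichment (``grid_spec`` cells per axis).  Cells with fewer than
    ``min_members`` members are merged into the nearest populated cell by
    standardized (log10 library size, log10 fold enrichment) centre distance.
    Every normal ends up in exactly one synthetic profile's provenance.
    """
    if not normals:
        raise ValueError("zero normals")
    for p in normals:
        if p.fold_enrichment is None:
            from .coverage import fold_enrichment

            p.fold_enrichment = fold_enrichment(p)
    matrix = exon_coverage_matrix(normals, grid, top_variance_k)
    labels = cluster_normals(matrix, min(n_clusters, len(normals)), method=linkage)

    all_ls = np.log10([p.library_size for p in normals])
    all_fe = np.log10([max(p.fold_enrichment, 1e-12) for p in normals])
    scale = (max(float(np.std(all_ls)), 1e-9), max(float(np.std(all_fe)), 1e-9))

    entries = []
    for cl in range(labels.max() + 1):
        members = [p for p, l in zip(normals, labels) if l == cl]
        ls = np.array([p.library_size for p in members], dtype=float)
        fe = np.array([p.fold_enrichment for p in members], dtype=float)
        na, nb = grid_spec
        ls_edges = np.quantile(ls, np.linspace(0, 1, na + 1))
        fe_edges = np.quantile(fe, np.linspace(0, 1, nb + 1))
        ci = np.clip(np.searchsorted(ls_edges[1:-1], ls, side="right"), 0, na - 1)
        cj = np.clip(np.searchsorted(fe_edges[1:-1], fe, side="right"), 0, nb - 1)
        cells = {}
        for idx, (a, b) in enumerate(zip(ci, cj)):
            cells.setdefault((int(a), int(b)), []).append(idx)

        def centre(idxs):
            return (
                np.mean(np.log10(ls[idxs])) / scale[0],
                np.mean(np.log10(np.maximum(fe[idxs], 1e-12))) / scale[1],
            )

        keep = {c: v for c, v in cells.items() if len(v) >= min_members}
        if not keep:  # whole cluster collapses to one cell
            keep = {max(cells, key=lambda c: (len(cells[c]), -c[0], -c[1])): []}
            keep = {next(iter(keep)): sum((cells[c] for c in sorted(cells)), [])}
        else:
            for c in sorted(set(cells) - set(keep)):
                cc = centre(cells[c])
                tgt = min(
                    sorted(keep),
                    key=lambda k: (
                        (centre(keep[k])[0] - cc[0]) ** 2 + (centre(keep[k])[1] - cc[1]) ** 2,
                        k,
                    ),
                )
                keep[tgt] = keep[tgt] + cells[c]

        for cell in sorted(keep):
            idxs = sorted(keep[cell])
            mem = [members[i] for i in idxs]
            prof = _average_profile(mem, f"synthetic_c{cl}_{cell[0]}_{cell[1]}", grid)
            entries.append(
                SyntheticEntry(
                    cluster=cl,
                    cell=cell,
                    ls_range=(float(ls_edges[cell[0]]), float(ls_edges[cell[0] + 1])),
                    fe_range=(float(fe_edges[cell[1]]), float(fe_edges[cell[1] + 1])),
                    profile=prof,
                    members=[p.sample_id for p in mem],
                )
            )
    return NormalLibrary(
        entries=entries,
        cluster_labels={p.sample_id: int(l) for p, l in zip(normals, labels)},
        grid=grid,
        scale=scale,
    )


def _candidate_for_cluster(library: NormalLibrary, cluster: int, ls: float, fe: float):
    """Cell containing (ls, fe), else nearest cell centre in standardized log10 space."""
    ents = [e for e in library.entries if e.cluster == cluster]
    inside = [
        e for e in ents
        if e.ls_range[0] <= ls <= e.ls_range[1] and e.fe_range[0] <= fe <= e.fe_range[1]
    ]
    if inside:
        return inside[0]
    lls, lfe = np.log10(max(ls, 1e-12)), np.log10(max(fe, 1e-12))

    def dist(e):
        cl = np.log10(max(np.mean(e.ls_range), 1e-12)) - lls
        cf = np.log10(max(np.mean(e.fe_range), 1e-12)) - lfe
        return (cl / library.scale[0]) ** 2 + (cf / library.scale[1]) ** 2

    return min(ents, key=lambda e: (dist(e), e.cell))


def select_synthetic(
    tumor: CoverageProfile, library: NormalLibrary, min_normal_count: float = 20
):
    """Pick the synthetic normal minimizing MSSD of the tumor/synthetic ratios.

    One candidate cell per cluster (matched on library size and fold
    enrichment); ties break toward the smallest cluster index.  Returns
    ``(profile, MssdScore)``.
    """
    if len(library) == 0:
        raise ValueError("empty normal library")
    from .coverage import fold_enrichment

    fe = tumor.fold_enrichment if tumor.fold_enrichment is not None else fold_enrichment(tumor)
    best = None
    n_clusters = max(e.cluster for e in library.entries) + 1
    for cl in range(n_clusters):
        cand = _candidate_for_cluster(library, cl, tumor.library_size, fe)
        try:
            score = mssd(read_ratio(tumor, cand.profile, min_normal_count))
        except ValueError:
            continue
        if best is None or score.value < best[1].value:
            best = (cand.profile, score)
    if best is None:
        raise ValueError("no candidate synthetic shares enough defined bins with the tumor")
    return best


def knn_synthetic(
    tumor: CoverageProfile, normals: list, k: int = 5, min_normal_count: float = 20
) -> CoverageProfile:
    """Per-bin median of the k normals with the smallest MSSD against the tumor."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(normals):
        raise ValueError(f"k={k} exceeds pool of {len(normals)} normals")
    scores = []
    for i, p in enumerate(normals):
        scores.append((mssd(read_ratio(tumor, p, min_normal_count)).value, i))
    scores.sort()  # ties: stable by input order
    chosen = [normals[i] for _, i in scores[:k]]
    norm = np.stack([p.counts / p.library_size for p in chosen])
    mean_ls = float(np.mean([p.library_size for p in chosen]))
    counts = np.median(norm, axis=0) * mean_ls
    prof = CoverageProfile(
        sample_id=f"knn{k}_{tumor.sample_id}", role="synthetic",
        counts=counts, library_size=mean_ls, grid=tumor.grid,
        meta={"members": [p.sample_id for p in chosen]},
    )
    if tumor.grid.target_flag.any():
        from .coverage import fold_enrichment

        prof.fold_enrichment = fold_enrichment(prof)
    return prof


def save_library(library: NormalLibrary, outdir) -> None:
    """Serialize a library to count TSVs plus a JSON manifest."""
    from .io import write_counts_tsv

    os.makedirs(outdir, exist_ok=True)
    manifest = {"scale": list(library.scale), "cluster_labels": library.cluster_labels,
                "entries": []}
    for e in library.entries:
        fname = f"{e.profile.sample_id}.tsv"
        write_counts_tsv(os.path.join(outdir, fname), e.profile)
        manifest["entries"].append(
            {"cluster": e.cluster, "cell": list(e.cell), "ls_range": list(e.ls_range),
             "fe_range": list(e.fe_range), "members": e.members, "file": fname}
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_library(indir, grid: BinGrid) -> NormalLibrary:
    from .io import read_counts_tsv

    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    entries = []
    for e in manifest["entries"]:
        prof = read_counts_tsv(os.path.join(indir, e["file"]), grid)
        entries.append(
            SyntheticEntry(
                cluster=e["cluster"], cell=tuple(e["cell"]),
                ls_range=tuple(e["ls_range"]), fe_range=tuple(e["fe_range"]),
                profile=prof, members=e["members"],
            )
        )
    return NormalLibrary(
        entries=entries, cluster_labels=manifest["cluster_labels"],
        grid=grid, scale=tuple(manifest["scale"]),
    )
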