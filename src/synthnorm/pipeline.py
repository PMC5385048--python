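"""End-to-end orchestration: normal selection -> ratio -> anchor -> segment -> call.

``run_pipeline`` is a pure function of (inputs, resolved config, seed): every
stage is seeded, stage outputs are persisted under the output directory, and
a resolved-config JSON records the exact parameters used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

from . import anchor as anchor_mod
from . import calling, cbs, evaluate, io, library

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline defaults; thresholds follow the method's published settings."""

    bin_width: int = 100_000
    min_normal_count: float = 20        # min normal reads per informative bin
    maf_threshold: float = 0.45         # candidate copy-neutral bins
    maf_min_depth: int = 10
    cbs_alpha: float = 0.01
    cbs_permutations: int = 2000
    cbs_min_width: int = 2
    seed: int = 0
    gain_log2: float = 0.25
    loss_log2: float = -0.32
    strategy: str = "library"           # "library" | "knn"
    k: int = 5
    n_clusters: int = 7
    library_grid: tuple = (3, 3)
    library_min_members: int = 3
    top_variance_k: int = 2500

    def caller_config(self) -> calling.CallerConfig:
        return calling.CallerConfig(gain_log2=self.gain_log2, loss_log2=self.loss_log2)


def run_pipeline(
    config: RunConfig,
    tumor,
    normals=None,
    normal_library=None,
    maf=None,
    truth_intervals=None,
    outdir=None,
):
    """Run the full calling workflow for one tumor.

    Parameters
    ----------
    tumor : CoverageProfile
    normals : list of CoverageProfile, optional
        Pool for library construction or KNN.
    normal_library : NormalLibrary, optional
        Pre-built library (skips construction).
    maf : MafTrack, optional
        Minor-allele-fraction track for diploid anchoring.
    truth_intervals : list of GenomicInterval, optional
        Altered territory of a ground truth; triggers evaluation.
    outdir : str, optional
        Directory for stage artifacts (SEG, purity JSON, eval TSV, config).

    Returns a dict with every stage product.
    """
    t0 = time.time()
    grid = tumor.grid

    if config.strategy == "library":
        if normal_library is None:
            if not normals:
                raise ValueError(
                    "strategy='library' needs normals or a pre-built library; "
                    "for small pools use strategy='knn'"
                )
            n_clusters = min(config.n_clusters, len(normals))
            normal_library = library.build_library(
                normals, grid, n_clusters=n_clusters,
                grid_spec=config.library_grid,
                min_members=config.library_min_members,
                top_variance_k=config.top_variance_k,
            )
        synthetic, score = library.select_synthetic(
            tumor, normal_library, config.min_normal_count
        )
    elif config.strategy == "knn":
        if not normals:
            raise ValueError("strategy='knn' needs a pool of normals")
        synthetic = library.knn_synthetic(tumor, normals, config.k, config.min_normal_count)
        from .coverage import read_ratio

        score = library.mssd(read_ratio(tumor, synthetic, config.min_normal_count))
    else:
        raise ValueError(f"unknown strategy {config.strategy!r}")

    from .coverage import read_ratio

    track = read_ratio(tumor, synthetic, config.min_normal_count)
    fitted = anchor_mod.fit_diploid_anchor(
        track, maf, maf_threshold=config.maf_threshold, seed=config.seed
    )
    adjusted = anchor_mod.apply_anchor(track, fitted)
    segset = cbs.segment(
        adjusted, alpha=config.cbs_alpha, n_permutations=config.cbs_permutations,
        min_width=config.cbs_min_width, seed=config.seed,
    )
    maf_by_seg = calling.segment_median_maf(segset, maf) if maf is not None else None
    calls, purity = calling.fit_integer_cn(segset, maf_by_seg, config.caller_config())

    result = {
        "synthetic": synthetic,
        "mssd": score,
        "track": adjusted,
        "anchor": fitted,
        "segments": segset,
        "calls": calls,
        "purity": purity,
        "library": normal_library,
    }

    if truth_intervals is not None:
        space = evaluate.merge_intervals(
            [grid.interval_of(i) for i in range(grid.n_bins) if grid.usable_flag[i]]
        )
        result["eval"] = evaluate.overlap_stats(
            evaluate.altered_intervals(calls), truth_intervals, space, tumor.sample_id
        )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        io.write_seg(os.path.join(outdir, f"{tumor.sample_id}.seg"), segset, calls)
        with open(os.path.join(outdir, f"{tumor.sample_id}.purity.json"), "w") as fh:
            json.dump(
                {"purity": purity.purity, "flag": purity.flag,
                 "diagnostics": {k: v for k, v in purity.diagnostics.items()
                                 if k != "candidate_grid"}},
                fh, indent=1, sort_keys=True, default=str,
            )
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            cfg = dataclasses.asdict(config)
            cfg["library_grid"] = list(config.library_grid)
            json.dump(cfg, fh, indent=1, sort_keys=True)
        if "eval" in result:
            ev = result["eval"]
            with open(os.path.join(outdir, f"{tumor.sample_id}.eval.tsv"), "w") as fh:
                fh.write("sample\tjaccard\tsensitivity\tspecificity\tevaluated_space\n")
                fh.write(
                    f"{ev.sample_id}\t{ev.jaccard:.6f}\t{ev.sensitivity:.6f}\t"
                    f"{ev.specificity:.6f}\t{ev.evaluated_space}\n"
                )
    logger.info("pipeline for %s finished in %.1fs", tumor.sample_id, time.time() - t0)
    return result
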