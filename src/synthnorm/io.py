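"""Readers and writers: BED, per-bin count TSV, SEG tables, allele-count tables.

All in-memory coordinates are 0-based half-open.  BED is native; SEG is
written 1-based inclusive (the format's convention) and converted back on
read.  Count TSVs carry sample metadata in ``#key=value`` header comments so
a profile round-trips exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .intervals import BinGrid, GenomicInterval


def read_bed(path) -> list:
    """Read a 3+ column BED into a list of :class:`GenomicInterval`."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {ln}: {line!r}")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ValueError(f"{path}: malformed BED line {ln}: {e}") from e
    return out


def read_named_bed(path) -> list:
    """Read a BED with a name column; returns [(name, GenomicInterval), ...]."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: BED line {ln} lacks a name column")
            out.append((parts[3], GenomicInterval(parts[0], int(parts[1]), int(parts[2]))))
    return out


def write_bed(path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_counts_tsv(path, profile: CoverageProfile) -> None:
    """Write a per-bin count table (chrom, start, end, count) with metadata."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#role={profile.role}\n")
        fh.write(f"#library_size={profile.library_size!r}\n")
        if profile.fold_enrichment is not None:
            fh.write(f"#fold_enrichment={profile.fold_enrichment!r}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        g = profile.grid
        for i in range(g.n_bins):
            c = profile.counts[i]
            c_str = repr(float(c))
            fh.write(f"{g.chroms[g.chrom_index[i]]}\t{g.starts[i]}\t{g.ends[i]}\t{c_str}\n")


def read_counts_tsv(path, grid: BinGrid) -> CoverageProfile:
    """Read a count table written by :func:`write_counts_tsv` against ``grid``.

    Every row must match a grid bin exactly, in grid order.
    """
    meta = {}
    rows = []
    with open(path) as fh:
        header_seen = False
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k] = v
                continue
            if not header_seen:
                header_seen = True  # column header
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed count row at line {ln}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3]), ln))
    if len(rows) != grid.n_bins:
        raise ValueError(
            f"{path}: {len(rows)} count rows do not match grid with {grid.n_bins} bins"
        )
    counts = np.empty(grid.n_bins)
    for i, (chrom, start, end, count, ln) in enumerate(rows):
        if (
            chrom != grid.chroms[grid.chrom_index[i]]
            or start != grid.starts[i]
            or end != grid.ends[i]
        ):
            raise ValueError(f"{path}: row at line {ln} does not match grid bin {i}")
        counts[i] = count
    fe = meta.get("fold_enrichment")
    return CoverageProfile(
        sample_id=meta.get("sample_id", "sample"),
        role=meta.get("role", "normal"),
        counts=counts,
        library_size=float(meta.get("library_size", counts.sum())),
        grid=grid,
        fold_enrichment=float(fe) if fe is not None else None,
    )


SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_bins", "seg_mean_log2"]
CALL_COLUMNS = SEG_COLUMNS + ["integer_cn", "call", "posterior"]


def write_seg(path, segset, calls=None) -> None:
    """Write segments (optionally with integer CN calls) as a SEG table.

    Coordinates are written 1-based inclusive per SEG convention (noted in
    the header comment).
    """
    cols = CALL_COLUMNS if calls is not None else SEG_COLUMNS
    with open(path, "w") as fh:
        fh.write("#coordinates=1-based inclusive (SEG convention)\n")
        fh.write("\t".join(cols) + "\n")
        if calls is not None:
            for c in calls:
                s = c.segment
                fh.write(
                    f"{segset.sample_id}\t{s.interval.chrom}\t{s.interval.start + 1}\t"
                    f"{s.interval.end}\t{s.n_bins}\t{s.mean_log2:.6f}\t"
                    f"{c.integer_cn}\t{c.direction:+d}\t{c.posterior:.6f}\n"
                )
        else:
            for s in segset.segments:
                fh.write(
                    f"{segset.sample_id}\t{s.interval.chrom}\t{s.interval.start + 1}\t"
                    f"{s.interval.end}\t{s.n_bins}\t{s.mean_log2:.6f}\n"
                )


def read_seg(path) -> pd.DataFrame:
    """Read a SEG table back to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["start"] = df["start"] - 1
    return df


def read_sites_tsv(path) -> pd.DataFrame:
    """Read a per-site allele-count table: chrom, pos (0-based), ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "ref_count", "alt_count"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: site table needs columns {sorted(need)}")
    return df


def write_sites_tsv(path, sites: pd.DataFrame) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites_vcf(path) -> pd.DataFrame:
    """Extract biallelic-SNV allele depths (AD) from a VCF into a site table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue
            for sample in rec.samples.values():
                ad = sample.get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    continue
                rows.append((rec.contig, rec.start, int(ad[0]), int(ad[1])))
                break
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref_count", "alt_count"])
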