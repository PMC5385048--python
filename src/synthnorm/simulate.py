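"""Synthetic cohorts with known copy-number truth.

The generator emulates the structure of whole-exome coverage data that the
rest of the package consumes:

* a target design of short exons concentrated in "genic" bins, so the grid
  has distinct on- and off-target territory;
* protocol-specific capture efficiency: each protocol draws a multiplicative
  log-normal efficiency per exon plus a dropout subset captured at a small
  fraction of nominal efficiency — the batch structure that clustering and
  synthetic-normal selection must recover;
* per-sample library size and fold-enrichment variation, plus a small
  per-bin log-normal jitter;
* tumors as piecewise-constant integer copy number diluted by purity, with
  negative-binomial count noise (capture data are overdispersed) and
  beta-binomial allele depths at planted heterozygous sites.

It does not emulate GC waves, mappability artifacts, subclonal mixtures or
read-level errors; conclusions from passing tests are about the method's
statistical machinery, not those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anchor import MafTrack, maf_track
from .calling import expected_log2
from .cbs import Segment, SegmentSet
from .coverage import CoverageProfile, fold_enrichment
from .intervals import BinGrid, GenomicInterval, build_bin_grid, classify_bins


def _default_truth():
    # bin-aligned, cn per segment; one-copy gain, loss, two-copy gain,
    # homozygous deletion, one-copy gain
    return [
        ("chr1", 5_000_000, 11_000_000, 3),
        ("chr1", 20_000_000, 24_000_000, 1),
        ("chr2", 2_000_000, 8_000_000, 4),
        ("chr2", 15_000_000, 16_000_000, 0),  # hom-dels are focal
        ("chr3", 10_000_000, 16_000_000, 3),
    ]


@dataclass
class SimScenario:
    """Full specification of a simulated study; same seed, same bytes out."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_000_000}
    )
    bin_width: int = 100_000
    genic_bin_period: int = 3      # every k-th bin carries exons
    exons_per_genic_bin: int = 10
    exon_length: int = 300
    n_protocols: int = 2
    protocol_dropout_fraction: float = 0.10
    dropout_factor: float = 0.05
    exon_sigma: float = 0.30       # log-normal per-exon efficiency spread
    sample_jitter_sigma: float = 0.05
    library_size_range: tuple = (8e6, 3e7)
    enrichment_range: tuple = (30.0, 60.0)
    truth_segments: list = field(default_factory=_default_truth)
    purity: float = 0.7
    # NB dispersion: var = mu + dispersion * mu^2.  Calibrated so a tumor vs
    # synthetic-normal ratio track has MSSD ~ 0.02, the scale reported for
    # well-matched exome pairs; together with the per-bin jitter this puts
    # per-bin rr CV near 10%.
    dispersion: float = 0.005
    noise: str = "nb"              # "nb" | "poisson" | "none"
    # Het-site allele depths.  Depth and overdispersion are set so the
    # per-bin median minor-allele fraction of balanced diploid territory
    # (~0.46 after the folding bias of min(ref,alt)/depth) clears the 0.45
    # copy-neutral candidacy threshold, as it does in adequately covered
    # exome data.
    het_site_spacing: int = 2000
    site_depth: float = 120.0
    maf_overdispersion: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        spans = sorted((c, s, e) for c, s, e, _ in self.truth_segments)
        for (c1, s1, e1), (c2, s2, _) in zip(spans[:-1], spans[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("truth segments overlap")
        if any(cn < 0 for *_, cn in self.truth_segments):
            raise ValueError("truth cn must be >= 0")

    def build_grid(self) -> BinGrid:
        grid = build_bin_grid(self.chrom_lengths, self.bin_width)
        return classify_bins(grid, self.targets())

    def targets(self) -> list:
        """Deterministic exon design: exons evenly placed in genic bins."""
        out = []
        step = self.bin_width // self.exons_per_genic_bin
        for chrom, ln in self.chrom_lengths.items():
            n_full = ln // self.bin_width
            for b in range(0, n_full, self.genic_bin_period):
                bstart = b * self.bin_width
                for e in range(self.exons_per_genic_bin):
                    s = bstart + e * step + step // 2
                    out.append(GenomicInterval(chrom, s, s + self.exon_length))
        return out


def _protocol_efficiencies(scenario: SimScenario):
    """Per-protocol multiplicative efficiency for every exon (deterministic)."""
    rng = np.random.default_rng([scenario.seed, 7])
    n_exons = len(scenario.targets())
    effs = []
    for _ in range(scenario.n_protocols):
        eff = rng.lognormal(mean=0.0, sigma=scenario.exon_sigma, size=n_exons)
        drop = rng.random(n_exons) < scenario.protocol_dropout_fraction
        eff[drop] *= scenario.dropout_factor
        effs.append(eff)
    return effs


def _rate_cache(scenario: SimScenario, grid: BinGrid) -> dict:
    """Per-(scenario, grid) cache: background mass and per-protocol exon mass."""
    cache = scenario.__dict__.get("_rate_cache")
    if cache is not None and cache["grid"] is grid:
        return cache
    targets = scenario.targets()
    exon_bin = np.array([grid.bin_of(t.chrom, t.start) for t in targets])
    exon_len = np.array([t.length for t in targets], dtype=float)
    ok = exon_bin >= 0
    background = (grid.ends - grid.starts).astype(float)  # 1 read mass per bp
    masses = []
    for eff in _protocol_efficiencies(scenario):
        mass = np.zeros(grid.n_bins)
        np.add.at(mass, exon_bin[ok], (exon_len * eff)[ok])
        masses.append(mass)
    cache = {"grid": grid, "background": background, "exon_mass": masses}
    scenario.__dict__["_rate_cache"] = cache
    return cache


def _bin_rates(scenario: SimScenario, grid: BinGrid, protocol: int, enrichment: float):
    """Expected relative read mass per bin for a diploid genome."""
    cache = _rate_cache(scenario, grid)
    return cache["background"] + enrichment * cache["exon_mass"][protocol]


def _sample_counts(rng, mu: np.ndarray, scenario: SimScenario) -> np.ndarray:
    if scenario.noise == "none":
        return mu.copy()
    if scenario.noise == "poisson":
        return rng.poisson(mu).astype(float)
    if scenario.noise == "nb":
        a = scenario.dispersion
        lam = rng.gamma(shape=1.0 / a, scale=a * mu)
        return rng.poisson(lam).astype(float)
    raise ValueError(f"unknown noise model {scenario.noise!r}")


def _draw_sample_params(rng, scenario: SimScenario):
    ls = rng.uniform(*scenario.library_size_range)
    enr = rng.uniform(*scenario.enrichment_range)
    return ls, enr


def simulate_normal(
    scenario: SimScenario, sample_index: int, grid: BinGrid | None = None
) -> CoverageProfile:
    """One diploid normal; protocol assignment is ``sample_index % n_protocols``."""
    grid = grid if grid is not None else scenario.build_grid()
    rng = np.random.default_rng([scenario.seed, 1, sample_index])
    protocol = sample_index % scenario.n_protocols
    ls, enr = _draw_sample_params(rng, scenario)
    rates = _bin_rates(scenario, grid, protocol, enr)
    if scenario.sample_jitter_sigma > 0:
        rates = rates * rng.lognormal(0.0, scenario.sample_jitter_sigma, size=len(rates))
    mu = rates / rates.sum() * ls
    counts = _sample_counts(rng, mu, scenario)
    prof = CoverageProfile(
        sample_id=f"normal{sample_index:03d}", role="normal", counts=counts,
        library_size=float(max(counts.sum(), 1.0)), grid=grid,
        meta={"protocol": protocol, "enrichment": enr, "drawn_library_size": ls},
    )
    prof.fold_enrichment = fold_enrichment(prof)
    return prof


def truth_cn_by_bin(scenario: SimScenario, grid: BinGrid) -> np.ndarray:
    cn = np.full(grid.n_bins, 2, dtype=int)
    for chrom, s, e, c in scenario.truth_segments:
        sel = (
            (grid.chrom_index == grid.chroms.index(chrom))
            & (grid.starts >= s)
            & (grid.ends <= e)
        )
        cn[sel] = c
    return cn


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated tumor."""

    segments: SegmentSet
    cn_by_bin: np.ndarray
    purity: float
    protocol: int
    library_size: float
    fold_enrichment: float

    def altered_intervals(self) -> list:
        return [
            GenomicInterval(c, s, e) for c, s, e, cn in self.segments.params["truth"]
            if cn != 2
        ]

    def truth_calls(self) -> list:
        from .calling import SegmentCall

        out = []
        for seg, (_, _, _, cn) in zip(self.segments.segments, self.segments.params["truth"]):
            out.append(
                SegmentCall(
                    segment=seg, integer_cn=cn, posterior=1.0,
                    direction=int(np.sign(cn - 2)),
                )
            )
        return out


def _truth_segset(scenario: SimScenario, grid: BinGrid) -> SegmentSet:
    segs = []
    for chrom, s, e, cn in scenario.truth_segments:
        sel = np.nonzero(
            (grid.chrom_index == grid.chroms.index(chrom))
            & (grid.starts >= s)
            & (grid.ends <= e)
            & grid.usable_flag
        )[0]
        segs.append(
            Segment(
                interval=GenomicInterval(chrom, s, e),
                n_bins=len(sel),
                mean_log2=expected_log2(cn, scenario.purity),
                p_value=0.0,
                bin_indices=sel,
            )
        )
    return SegmentSet(
        sample_id="truth", segments=segs, params={"truth": list(scenario.truth_segments)}
    )


def _minor_fraction(cn: int, purity: float) -> float:
    """Expected minor allele fraction: gains amplify one allele, losses drop one."""
    m = 0 if cn <= 1 else 1
    denom = purity * cn + (1 - purity) * 2
    if denom <= 0:
        return 0.5
    return (purity * m + (1 - purity) * 1) / denom


def simulate_tumor(
    scenario: SimScenario,
    matched_protocol: int = 0,
    tumor_index: int = 0,
    grid: BinGrid | None = None,
    with_maf: bool = True,
):
    """One tumor with known truth; returns ``(profile, maf_track, truth)``.

    Expected counts are the protocol's diploid expectation scaled per bin by
    the purity-dilution factor (purity * cn + 2 * (1 - purity)) / 2.  Allele
    depths at planted heterozygous sites are beta-binomial around the
    cn/purity-consistent minor fraction.
    """
    grid = grid if grid is not None else scenario.build_grid()
    rng = np.random.default_rng([scenario.seed, 2, tumor_index])
    ls, enr = _draw_sample_params(rng, scenario)
    rates = _bin_rates(scenario, grid, matched_protocol, enr)
    if scenario.sample_jitter_sigma > 0:
        rates = rates * rng.lognormal(0.0, scenario.sample_jitter_sigma, size=len(rates))
    cn = truth_cn_by_bin(scenario, grid)
    dilution = (scenario.purity * cn + 2.0 * (1.0 - scenario.purity)) / 2.0
    rates = rates * dilution
    mu = rates / rates.sum() * ls
    counts = _sample_counts(rng, mu, scenario)
    prof = CoverageProfile(
        sample_id=f"tumor{tumor_index:03d}", role="tumor", counts=counts,
        library_size=float(max(counts.sum(), 1.0)), grid=grid,
        meta={"protocol": matched_protocol, "enrichment": enr},
    )
    prof.fold_enrichment = fold_enrichment(prof)

    maf = None
    if with_maf:
        sites = _simulate_sites(scenario, grid, cn, rng)
        maf = maf_track(sites, grid)

    truth = SimTruth(
        segments=_truth_segset(scenario, grid),
        cn_by_bin=cn,
        purity=scenario.purity,
        protocol=matched_protocol,
        library_size=float(counts.sum()),
        fold_enrichment=prof.fold_enrichment,
    )
    return prof, maf, truth


def _simulate_sites(scenario, grid, cn_by_bin, rng) -> pd.DataFrame:
    rows_chrom, rows_pos, rows_ref, rows_alt = [], [], [], []
    rho = scenario.maf_overdispersion
    conc = (1.0 - rho) / rho if rho > 0 else None
    for i in np.nonzero(grid.usable_flag)[0]:
        chrom = grid.chroms[grid.chrom_index[i]]
        f = _minor_fraction(int(cn_by_bin[i]), scenario.purity)
        pos = np.arange(
            grid.starts[i] + scenario.het_site_spacing // 2,
            grid.ends[i],
            scenario.het_site_spacing,
        )
        depth = rng.poisson(scenario.site_depth, size=len(pos))
        if conc is not None and 0 < f < 1:
            p = rng.beta(f * conc, (1 - f) * conc, size=len(pos))
        else:
            p = np.full(len(pos), f)
        alt = rng.binomial(depth, p)
        rows_chrom.extend([chrom] * len(pos))
        rows_pos.extend(pos.tolist())
        rows_alt.extend(alt.tolist())
        rows_ref.extend((depth - alt).tolist())
    return pd.DataFrame(
        {"chrom": rows_chrom, "pos": rows_pos, "ref_count": rows_ref, "alt_count": rows_alt}
    )


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The package's reference study: 3 x 30 Mb chromosomes, 100-kb bins,
    5 truth segments, purity 0.7, 2 protocols."""
    return SimScenario(seed=seed, **overrides)
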