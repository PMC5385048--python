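# Methods

## Problem and approach

Copy-number alteration (CNA) calling from whole-exome sequencing usually
compares tumor read depth against a matched normal. Exome capture is not a
neutral step: capture efficiency varies per exon, per protocol version, and
per library, so a tumor/normal pair that differs in capture characteristics
shows ratio artifacts that mimic CNAs. `synthnorm` replaces the matched
normal with a *synthetic normal* chosen from a pool of normals to match the
tumor's capture behaviour, then carries the standard CNA machinery:
segmentation, integer copy number, purity.

The pipeline stages and the model behind each:

1. **Binning.** The genome is tiled with fixed-width, non-overlapping bins
   (default 100 kb; 10/20/50 kb supported). Bins overlapping any capture
   target (≥1 bp) are *on-target*; trailing partial bins are kept in the
   grid but excluded from every statistic, preserving the fixed-width
   assumption. A bin is informative only when the normal provides at least
   `min_normal_count` reads (default 20).

2. **Read ratios.** rr_i = (t_i/T)/(n_i/N) with T, N the library sizes, so a
   balanced diploid bin sits at 1 regardless of sequencing depth. The ratio
   difference (RD) between adjacent bins — stratified into on/on, off/off
   and mixed adjacency classes — diagnoses capture bias: in a well-matched
   pair the three RD distributions coincide.

3. **Technical-noise score.** The mean square successive difference,
   MSSD = Σ (rr_{i+1} − rr_i)² / n_pairs, over within-chromosome pairs of
   adjacent informative bins. Under a piecewise-constant copy-number signal
   the successive differences are almost everywhere pure technical noise, so
   MSSD ranks tumor/normal pairings by artifact level. The divisor is the
   pair count (no factor ½) — any positive scaling is selection-invariant.

4. **Synthetic-normal library.** Normals are clustered by capture signature:
   library-size-normalized coverage of the most variable capture units (top
   2500 by variance), mean-centred, hierarchically clustered (Euclidean,
   complete linkage) and cut to `n_clusters` groups (default 7). When built
   from per-bin profiles the capture units are the on-target usable bins;
   the protocol dropout signature survives aggregation to 100-kb resolution,
   and a per-exon matrix computed externally can be supplied instead.
   Within each cluster a quantile grid (default 3×3) over (library size,
   fold enrichment) is built; cells with fewer than `min_members` (default
   3) normals are merged into the nearest populated cell by standardized
   (log10 library size, log10 fold enrichment) distance. Each surviving
   cell's members are averaged on the normalized-count scale and rescaled to
   their mean library size. For a tumor, one candidate cell per cluster is
   matched on (library size, fold enrichment) and the winner minimizes the
   MSSD of the tumor/synthetic ratio track; ties break to the smallest
   cluster index.

   The **KNN strategy** needs no library: every normal is scored by MSSD
   against the tumor and the per-bin median of the best k (default 5) is the
   synthetic normal. It suits small pools or drifting protocols.

   Fold enrichment is the ratio-of-fractions (on-target reads / total) /
   (target bases / genome bases). From per-bin counts it is approximated at
   bin resolution (reads in target bins over target-bin bases); callers with
   read-level numbers can supply them exactly. Both inputs to the library
   grid only need to rank samples consistently.

5. **Diploid anchoring.** Aneuploidy breaks "average ratio = diploid".
   Bins whose median minor-allele fraction (MAF) exceeds 0.45 are candidate
   copy-neutral territory (site MAF = min(ref,alt)/depth over sites with
   depth ≥ 10 and both alleles seen). Gaussian mixtures with 1..5 components
   are EM-fitted to the candidate ratios (10 k-means++ restarts, tol 1e-6,
   ≤500 iterations, seeded) and the BIC-minimal model is kept. The diploid
   component is the smallest-mean component **among components with weight
   ≥ 5%**, and all ratios are rescaled so its mean is exactly 1. The weight
   guard exists because homozygously deleted territory is allelically
   silent — its residual reads come from contaminating normal cells, so its
   median MAF sits near 0.5 and it enters the candidate set — but being
   focal it can only form a minor component. Balanced higher-ploidy states
   (e.g. 2+2 tetraploid) sit at higher ratios, which is why the *smallest*
   eligible mean is diploid. With fewer than 30 candidate bins (or no MAF
   data) the fit falls back to all informative bins, with a logged warning.

6. **Segmentation.** Circular binary segmentation on log2(adjusted rr)
   (ratios floored at 1e-6 before the log). Each chromosome piece is treated
   as a circle; the arc maximizing |T| — the two-sample t-like statistic
   between arc and complement with pooled variance floored at 1e-12 — is the
   candidate split, accepted when its within-piece permutation p-value ≤ α
   (default 0.01; default 10,000 permutations, seeded; the permutation loop
   stops early once significance is impossible). An arc and its circular
   complement are the same split and tie structurally, so the argmax is
   defined as the lexicographically smallest (i, j) within relative
   tolerance 1e-9 of the maximum. Splits honour `min_width` (default 2
   bins); missing bins are skipped and never joined across. No undo-splits
   post-processing is applied. Segmenting in log2 space keeps the gain/loss
   thresholds symmetric-ish in variance and matches where the calling
   thresholds are defined.

7. **Integer copy number and purity.** Segment means are modelled as a
   normal mixture with means pinned at log2((p·c + 2(1−p))/2) for copy
   number c = 0..8 and purity p, shared variance estimated from the data
   (floored at 0.02), and an exponentially decaying prior ∝ exp(−|c−2|)
   centred on the diploid state. Purity is a grid search over p ∈ [0.05, 1]
   step 0.01, scoring the bin-count-weighted log marginal likelihood; ties
   resolve to the higher purity. The decay prior is what breaks the
   purity/ploidy confounding — (p=1, c∈{2,3}) and (p=0.5, c∈{2,4}) fit any
   data equally well, but the latter pays a larger prior penalty — so the
   caller prefers the higher-purity / lower-ploidy reading. Two heuristic
   filters then dissolve weakly supported copy levels into the nearest
   surviving level: levels with fewer than 2 segments, and a level whose
   median MAF is within 0.05 of a neighbouring level's (the cn=2 level is
   never dissolved; both knobs are exposed and logged, as neither has a
   canonical value). A genome whose segment means show no contrast is
   reported as purity 1 with an `unidentifiable` flag. Discrete direction
   calls use fixed log2 thresholds: gain > 0.25, loss < −0.32.

8. **Evaluation.** Calls and truth are compared as base-length interval sets
   within an evaluable space, by default the union of usable bins — not the
   whole genome, which would inflate specificity with unassayed territory.
   JI = |∩|/|∪|, sensitivity = |∩|/|truth|, specificity =
   |space∖(calls∪truth)|/|space∖truth|, with the usual empty-set
   conventions. Gene-level concordance converts each sample's segments into
   {−1, 0, +1} per gene (direction of the largest-overlap segment) and runs
   a per-gene paired Wilcoxon signed-rank test (zero-differences discarded;
   exact null for small n, normal approximation with continuity correction
   otherwise) with Benjamini–Hochberg control; a gene is discordant at
   q < 0.05. Cohort frequency landscapes report per-bin gain/loss fractions.

## The simulator

The generator emulates the data-generating structure the method targets:

* a deterministic exon design (10 × 300 bp exons in every third 100-kb bin,
  ≈1% of the genome on-target at base level, one third of bins on-target);
* per-protocol capture efficiency: a log-normal multiplicative efficiency
  per exon (σ = 0.3) plus a 10% dropout subset captured at 5% efficiency —
  the batch structure clustering must recover; a 5% log-normal per-bin
  per-sample jitter on top;
* per-sample library size uniform on 8–30 million reads and fold enrichment
  uniform on 30–60, the two axes of the library grid;
* tumors as piecewise-constant integer copy number (default: five
  bin-aligned segments on a 3 × 30 Mb genome — one-copy gains, a one-copy
  loss, a two-copy gain, and a focal 1 Mb homozygous deletion) diluted by
  purity (default 0.7);
* negative-binomial counts with dispersion 0.005, calibrated so a tumor vs
  synthetic-normal track has MSSD ≈ 0.02, the scale of a well-matched exome
  pair (Poisson and zero-noise modes exist for exact tests);
* heterozygous sites every 2 kb with beta-binomial allele depths (mean depth
  120, overdispersion 0.005) around the cn/purity-consistent minor fraction,
  modelling gains as single-allele amplifications. The min(ref,alt)/depth
  folding biases balanced territory to a median MAF ≈ 0.46, which clears the
  0.45 candidacy threshold as adequately covered exome data does.

Not emulated: GC waves, mappability artifacts, subclonal mixtures,
read-level errors, adaptive binning. Passing tests therefore demonstrate the
statistical machinery under the declared generative model, not robustness to
those artifacts.

## Numerical and design choices

* Reads are assigned to bins by leftmost aligned base; MAPQ ≥ 1,
  primary, non-duplicate only. The bin width dwarfs read length, so
  fractional overlap assignment would change almost nothing.
* Coordinates are 0-based half-open internally and in BED; SEG files are
  written 1-based inclusive (the format's convention) and converted on read.
* Chromosomes sort naturally (chr1..chr22, chrX, chrY).
* Quantile grid edges (rather than fixed absolute ranges) keep library
  cells populated for arbitrary cohorts.
* Simulation-heavy tests and the acceptance script use 200 CBS permutations
  at α = 0.01 (p-resolution 0.005) and the 3 × 30 Mb default scenario —
  problem sizes chosen to exercise every stage at full fidelity while
  keeping a study of dozens of seeds comfortable on one CPU.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Known limitations

* Focal events smaller than a bin are invisible; there is no adaptive
  binning.
* Allele-specific copy number and subclonal deconvolution are out of scope;
  MAF is used only for anchoring and level separation.
* Mixing normals from different protocols into one pool degrades selection
  quality; the library warns rather than forbids.
* The purity model assumes a single dominant clone and at most one
  whole-genome state per segment; whole-genome doubling can still be read
  as the lower-ploidy solution by the cn=2 prior.
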