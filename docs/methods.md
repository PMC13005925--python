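# Methods

## The problem

Copy-number variation (CNV) calling from hybrid-capture panel sequencing
relies entirely on read depth: the restricted footprint of a panel
leaves little split-read or insert-size evidence, so coverage over the
capture targets is the signal. That coverage is shaped at least as much
by capture efficiency, GC composition and batch structure as by copy
number. `ridgecnv` separates those nuisances from the signal with a
two-layer normalization — a panel of normals (PoN) for the shared
capture structure, and a per-sample ridge model for everything the PoN
cannot explain — and then segments the resulting log2-ratio profile
with a three-phase procedure before calling discrete copy states.

## Depth extraction and normalization

Fragments (properly paired reads, duplicates/secondary/supplementary/
QC-fail excluded, mapping quality >= 1 by default) are counted once per
target they overlap. Each sample's counts then pass through three
stages:

1. **Length**: `RD_l = RD_r / L` with `L` the target length in bp.
2. **GC**: a LOWESS fit of `RD_l` against per-target GC fraction
   (span 0.3, one robustifying iteration) gives `Fit`;
   `RD_GC = RD_l / (Fit / median(Fit))`. The fit is floored at
   `1e-3 * median(Fit)` so the correction can never divide by ~0.
   Soft-masked bases count toward GC; N bases are excluded from the
   denominator, and all-N targets are masked.
3. **Global**: `RD_nor = RD_GC / median(RD_GC)`, making samples
   cross-comparable regardless of library size.

The stage is carried on the vector and transitions are enforced in
order; `global_normalize` is scale-invariant and `gc_correct` preserves
the sample median up to the flooring epsilon.

## Panel of normals

The PoN is the region x sample matrix of `RD_nor` values from CNV-free
normal samples (white-blood-cell style baselines), summarized per region
by its median. Entries are post-global-normalization deliberately:
without per-sample median scaling, library size would dominate the
row medians. Regions whose baseline median falls below a depth floor
(default 0.05 — effectively uncapturable targets) or that lack a GC
value are masked from every downstream vector while keeping their panel
ordinals, so report coordinates stay stable. A persisted PoN carries a
digest of the panel coordinates and refuses to load against a different
panel. Per-sample QC (median |log2 sample − log2 median profile|) is
advisory only; nothing is dropped automatically.

## Stable-chromosome selection

For each autosome (chr1–chr22 only; sex chromosomes are excluded from
selection) two indices compare the test sample with the PoN median
profile over unmasked targets:

* `AL_c = |mean(log2 testRD − log2 baseRD)|` — systematic bias. The
  absolute value sits *outside* the mean, exactly as the procedure
  defines it, so balanced gains and losses on one chromosome can cancel;
  a `mean_of_abs` switch provides the stricter variant (default off).
* `PR_c` — Pearson correlation of the two depth vectors, measuring
  concordance of the coverage pattern.

Both are min–max scaled across eligible autosomes (those with >= 10
unmasked targets and a defined correlation); a spread below numerical
precision scales to all-zeros, since it carries no ranking information.
Each chromosome becomes a point `(NA_c, NP_c)` and the one closest to
the ideal `(0, 1)` in Euclidean distance `d` is the stable chromosome;
ties break to the lowest-numbered autosome. A pseudocount of `1e-3`
inside both logarithms tolerates sporadic zero depths.

A practical caveat found while validating this step: when a large
fraction of the panel (tens of percent) is copy-altered in one
direction, the sample's global median shifts and the *spared*
chromosome inherits a uniform log2 offset that inflates its `AL`. With
mixed gains and losses, or with realistic event loads, selection is
reliable (the spared autosome wins in 20/20 seeded trials of the
spiking experiment in the test suite).

## Ridge self-normalization

Let `X` (N x M) hold `log2(RD_nor + 1e-3)` of the PoN on the stable
chromosome's unmasked targets and `y` the test sample's values there.
Columns are standardized with the column mean and the *population*
standard deviation (divisor N); constant columns are dropped. With the
response and features centered, the closed-form ridge solution is

    w* = (Xc' Xc + alpha I)^-1 Xc' yc,     b* = mean(y) − w*' mean(X~)

solved through a Cholesky factorization of the symmetric
positive-definite system — never an explicit inverse. `alpha = 1.0` by
default (exposed as `--ridge-alpha`); N < M is fine because the penalty
regularizes the rank deficiency. The model, fitted only on the stable
chromosome, is applied to every unmasked target genome-wide (rows
standardized with the *training* column statistics), and the
self-normalized profile is `r_i = y_i − yhat_i`.

Known limitations, both visible in the test suite:

* the intercept inherits the sampling noise of one chromosome's mean
  (sd roughly `sigma / sqrt(N_train)`), so whole profiles wobble by a
  few hundredths of a log2 unit from sample to sample;
* a CNV on the training chromosome itself biases the profile
  genome-wide (the documented failure mode of any self-normalization);
* very heavy CNV loads leak into the sample's own GC fit and global
  median, attenuating amplified segments by ~0.05–0.1 log2.

## Segmentation

Three phases per chromosome.

**z-score pre-partitioning.** Scanning left to right, the mean and sd
(divisor n−1) of the expanding window since the last breakpoint are
maintained; the sd is floored at `min_sd = 0.05` and the first
`min_window = 5` points of a chromosome always join the open segment.
An incoming point with `|x − mu| / max(sd, min_sd) > 3` closes the
segment and *begins* the new one; the window statistics then restart.

**Kernel smoothing.** Within each pre-segment, distances between target
midpoints define `W_ij ∝ exp(−d_ij / lambda)` with
`lambda = range/4 + 1` (the `+1` floors the scale at 1 bp for
degenerate segments); rows are normalized to sum to one and the whole
pre-segment acts as the neighborhood. The smoothed value is the convex
combination `alpha * (W v) + (1 − alpha) * v`.

`alpha_smooth` defaults to **0.3**. The value is a free parameter of
the procedure, and the choice is driven by a calibration argument: the
final-phase permutation test treats points within a chromosome as
exchangeable, while smoothing deliberately shrinks within-segment
variance and correlates neighbors. At `alpha = 0.5` the null becomes
anti-conservative enough that long uniform events fragment into several
segments and weak flanking calls appear (measured precision dropped
from 0.80 to 0.65 on a development benchmark); at 0.3 the blended
profile stays close enough to the raw noise scale for the test to hold
its nominal level while still damping single-target excursions.

**Circular binary segmentation.** The smoothed profile of each
chromosome is segmented recursively: among all arcs `(i, j]` whose
induced pieces each span at least `min_width = 2` targets (the
canonical CBS minimum), the arc maximizing

    |mean(arc) − mean(complement)| / (sd * sqrt(1/m + 1/(n−m)))

is the candidate split, accepted when its permutation p-value is below
`cbs_alpha = 0.01` (up to 10,000 permutations). Permutations are drawn
one at a time from the seeded generator so the stream is independent of
internal batching; sequential early stopping abandons a test as soon as
a binomial confidence bound places the p-value clearly above or below
`alpha`. CBS is the final authority on breakpoints and may merge across
pre-segment boundaries. Segment *levels*, however, are re-estimated
from the original (unsmoothed) log2 ratios: smoothing exists to
stabilize breakpoints, and level estimates taken from blended values
would let signal smeared across an imperfect pre-segment boundary
masquerade as a weak flanking call.

All randomness flows from one seed through a `SeedSequence` spawned per
chromosome, so reruns are bitwise identical.

## Calling

Without a purity estimate, fixed log2 cutoffs in the convention of
established panel callers assign integer copy numbers: below −1.1 →
CN 0, below −0.25 → CN 1, up to 0.2 → CN 2, up to 0.7 → CN 3, else
`round(2 * 2^r)`. With purity `p` in (0, 1], the observed ratio is
inverted through the mixture model `2^r = (p CN + (1−p) 2) / 2` before
rounding. Segment means are clipped at −8 before inversion (CN 0 is a
log2 of −infinity in theory). States follow CN < 2 deletion, CN = 2
neutral, CN > 2 duplication; sex chromosomes are called against ploidy
2 with a warning. Gene annotation reports the length-weighted modal
state per gene, flags genes split by a breakpoint, and marks genes
whose targets are all masked as not evaluable.

## The benchmark simulator

The simulator works at depth level — per-target fragment counts, the
quantity the pipeline consumes — rather than at read level. The design
is fixed: 50 groups x 10 CNVs of random length (log-uniform, 5–100
targets) x 6 purities (0.2, 0.3, 0.4, 0.6, 0.8, 1.0), copy states
uniform over {0, 1, 3, 4, 5, 6, 8, 10}, i.e. 3000 truth events over
300 tumor samples, plus a PoN of diploid normals (M = 50 at the desk
scale used throughout; larger cohorts are a parameter).

Counts are negative binomial around

    mean_depth * (L_i / mean L) * eff_i * gcbias_s(gc_i) * wave_s(i)
              * (p CN_i + (1−p) 2) / 2

with `mean_depth = 400` and NB size 50 (per-target log2 noise ~0.2,
the regime of deep, deduplicated capture panels). `eff_i` is lognormal
(sigma 0.5) and shared by every sample of a run — the capture
structure a PoN exists to remove. Per sample, a quadratic GC curve
(coefficients ~ N(0, 0.5)), an AR(1) log-scale wave (sd 0.02, rho 0.7
— residual correlated noise surviving normalization) and sporadic
single-target outliers (rate 0.002, log-sd 1.0 — capture artifacts)
model what the self-normalization layer and the segmenter must cope
with. Event-level evaluation requires >= 50% reciprocal overlap (in
target-ordinal space) with concordant direction, greedy one-to-one
matching; sensitivity, precision and F1 are pooled over all samples.

What the generator does *not* emulate: read-level error profiles,
mappability structure, FFPE fragmentation biases, subclonal mixtures
beyond a single purity per sample, and recurrent artifact loci. Passing
benchmarks on this generator therefore demonstrate correct mechanics
and reasonable operating characteristics under a plausible noise model,
not clinical performance.

## Problem sizes and determinism

The shipped checks use a 2000-target panel over 22 autosomes, a PoN of
50, and 300 tumor samples for the operating-point benchmark; smaller
worlds (400–800 targets, PoN 8–20) for unit-level checks. Every
stochastic component is seeded, and the full pipeline rerun with the
same inputs and seed is byte-for-byte identical.

## External validation

The caller's clinical counterpart of this benchmark — concordance with
FISH at specific loci on real tumor cohorts — requires controlled-access
sequencing data and is out of scope here. The recipe is unchanged:
build a PoN from workflow-matched normals (`ridgecnv pon-build`), run
each tumor (`ridgecnv run`), and compare gene-level calls
(`genes.tsv`) against the orthogonal assay.
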