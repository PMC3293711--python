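# Methods

`regnorm` studies a question specific to two-channel *regulation*
microarrays (ChIP-on-chip, MeDIP-on-chip): which normalization strategies
remove technical biases without destroying the biological signal? On
these arrays the green (Cy3) channel carries total input DNA and the red
(Cy5) channel an immunoprecipitated, enriched sample, so the per-probe
log-ratio M = log2(R/G) is a measure of enrichment and its distribution
has two components — a majority un-enriched component and an enriched
component. Transcriptomics normalization methods assume most probes are
unchanged between channels; on regulation arrays that assumption fails,
and the package quantifies the damage.

## Separation metric

Negative-control probes (no genomic target; they measure non-specific
annealing and background fluorescence) form the negative class and gene
promoter probes the positive class of a ROC analysis on the log-ratios.
The AUC is computed both by a threshold sweep and by the Mann–Whitney
rank formula with half-credit ties; the two are required to agree to
1e-10, which also pins down the tie convention (ties produce diagonal ROC
segments whose trapezoids equal the half-credit count). AUC is invariant
under strictly increasing transforms of the scores — the formal reason
rank-preserving normalizations cannot change it. Per-array AUCs describe
each hybridization; the combined AUC pools probes across arrays and is
therefore additionally sensitive to between-array incomparability; the
across-array standard deviation of per-array AUCs quantifies
comparability directly.

## The six normalization methods

* **LOWESS** — per-array robust local regression of M on A (span 0.3,
  4 robustifying iterations by default), subtracted from M. Assumes the
  log-ratio is centered on zero at every intensity. With strong curvature
  the edge of the fitted range retains local-linear smoothing bias
  (~f″·h²), so detrending checks in the test-suite use span 0.2.
* **Quantile** — all 2·n channels (green and red together) mapped onto the
  mean sorted intensity vector (rank-wise arithmetic means on the raw
  intensity scale; ties receive the mean of their positions' scores). By
  construction every channel ends up with an identical distribution.
* **VSN-style** — per-channel affine calibration followed by the
  generalized log, h_c(x) = glog2((x − a_c)/b_c) with glog2(y) =
  log2(y + √(y²+1)). Parameters are estimated by a *trimmed Gaussian
  profile likelihood*: squared deviations of each probe's transformed
  values from their across-channel mean, summed over the 90% of probes
  with the smallest deviations (the "majority un-enriched" assumption),
  plus the log-Jacobian of the transforms. The Jacobian term is essential:
  without it, compressing a channel toward a constant trivially minimizes
  the disagreement and the fit becomes optimizer-path-dependent. The
  optimizer is L-BFGS-B with an analytic gradient, alternated with
  retained-set updates until stable; parameters are fitted on a
  deterministic intensity-stratified subsample of 2000 probes and the
  transform is then applied to all probes. This is a self-contained
  calibrated-glog model in the VSN family, not a port of any reference
  implementation.
* **T-quantile** — quantile normalization within subgroups: green channels
  equalized across arrays and red channels equalized across arrays,
  separately. Within-array within-channel ranks are preserved exactly
  while the red and green distributions remain free to differ — the
  property that protects the enriched component. Requires ≥ 2 arrays.
* **Tukey's biweight scaling (TBW)** — per-array subtraction of the
  biweight robust location of M: starting at the median with scale
  MAD, iterate weighted means with bisquare weights w = (1−u²)² for
  |u| < 1, u = (x − current)/(c·MAD), c = 5, tol 1e-6. A pure per-array
  shift, so per-array ROC curves are *identical* to raw data's (this
  identity is asserted to 1e-12). The combined AUC is not exactly
  invariant — different arrays are shifted by different constants, which
  permutes cross-array ranks — and the tests only assert exact pooled
  invariance for a shared global shift.
* **Peng's method** — total-least-squares (first principal direction)
  estimate of the major-axis slope of the (A, M) cloud, rotation about
  the centroid by −atan(slope), then LOWESS. The rotation makes a strong
  assumption about the shape of the MA plot; when the cloud's principal
  direction is driven by enrichment rather than dye bias, the rotation
  mixes intensity into the log-ratio. The angle is reported in the
  diagnostics.

## Two-component mixture

`fit_two_component_mixture` is a plain two-component Gaussian EM on the
log-ratios: deterministic given the initialization (means start at the
25th/90th percentiles), log-likelihood checked non-decreasing, components
ordered by mean, component collapse (sd < 1e-6) raised as an error. A
second component that does not improve the BIC relative to a single
Gaussian is flagged in the diagnostics. scikit-learn's `GaussianMixture`
serves as an independent cross-check in the tests, never as the
implementation.

## Sliding-window enrichment

Only the upper quantile of the log-ratio distribution is informative, so
the window test asks whether the probes around a position over-sample it.
The threshold is the empirical `threshold_quantile` (default 0.95) of the
*tiling-probe* log-ratios — the same universe the windows sample, so the
global margins K/N of the 2×2 table match the nominal quantile. For each
tiling probe, the window is all same-chromosome probes within
± window_bp/2; with k of n window probes above threshold against K of N
genome-wide, the p-value is half the upper tail of the Yates-corrected
chi-square (1 df) on [[k, n−k], [K−k, (N−n)−(K−k)]], set to 1 when
k/n ≤ K/N. Windows containing a single probe get p = 1 and a diagnostics
flag. Runs of probes with p < alpha are merged into regions across gaps
smaller than window_bp/2 (region boundaries are not standardized across
tools; the merge rule is a package choice). Because only the threshold
rank matters, p-values are invariant under strictly increasing transforms
of M — TBW-normalized and raw data give bit-identical calls. No
multiplicity correction is applied; region counts are reported at
p < 0.05/0.10/0.20/0.50.

## Synthetic data generator

The generator emulates a NimbleGen-style promoter/tiling experiment with
known truth. Layout: negative controls (chrC), promoter probes (chrP) and
a contiguously tiled region (chrT, default 100-bp spacing, 50-bp probes).
Per probe i and array j, on the log2 scale:

1. green = background_mean + probe_effect_i (N(0, background_sd)) +
   noise (N(0, noise_sd));
2. enrichment weight w_i: 0 for controls and un-enriched promoters,
   `partial_enrichment` (default 1) for enriched promoters; for tiling
   probes, w_i = exp(−d/L) with d the distance to the nearest planted
   site center and L the mean sonication fragment length — the
   probability that a random fragment covering the site also covers the
   probe under an exponential fragment-length tail, giving the
   characteristic correlated, unimodal peak over adjacent probes;
3. specific red signal = green + w_i · shift · efficiency_j, with
   efficiency_j ~ LogNormal(0, array_efficiency_sd) for between-array IP
   efficiency. When `red_background_log2` is set (it is, in both
   presets), the red intensity is w_i·2^specific + 2^(floor + noise): a
   probe whose target is absent from the precipitate measures only
   background fluorescence, *uncorrelated* with its green signal and
   compressed into a narrow band. This is the structural feature that
   makes channel-pooling normalizations destructive — a rank map onto a
   wide reference distribution stretches the narrow background noise
   across the dynamic range of the enriched component;
4. observed biases: M ← scale_j·M + poly(dye_trend_coeffs, A −
   background_mean) + offset_j (scale LogNormal, offset normal), then a
   per-array per-channel gain LogNormal(0, channel_gain_sd) applied to
   the centered channel log-intensities (scanner/photo-multiplier
   response differences). Intensities are exponentiated, hence positive.

Identical config + seed is bit-reproducible (a single `default_rng`
stream).

### Presets and their calibration

Two presets ship as YAML files mirroring `SimulationConfig`
field-for-field. Both model promoter-dominated 40k-probe arrays (30k
promoter, 6k tiling, 4k control), background_mean 10, background_sd 1,
noise_sd 0.3, red background floor 2^8.5 (≈ 3× below mean input),
enrichment_shift 1.2, efficiency sd 0.3, channel gain sd 0.10, M-offset
sd 0.3, M-scale sd 0.10, quadratic dye trend (0.08·x + 0.04·x²). They
differ only in the enriched fraction and planted-site count:
**chip-like** (4 arrays, 2% of promoters enriched, 5 sites) produces
largely overlapping control/promoter densities; **medip-like** (8 arrays,
35% enriched, 20 sites) produces visibly separated ones, reflecting that
methylated CpGs cover a substantial share of a genome while transcription
factor binding sites do not.

The calibration targets the *raw-data* structure of real studies:
separated-but-overlapping class densities (not saturated — with a deeper
separation every method scores the same AUC and the comparison is
uninformative), visible between-array variation in per-array AUC
(sd ≈ 0.003–0.01) that between-array normalization can reduce, and red
channels whose distribution genuinely differs from the green channels'.
Under these conditions the package reproduces, as measured outcomes
rather than assumptions: T-quantile and TBW preserve the combined AUC
while quantile, LOWESS, VSN-style and Peng lower it; T-quantile roughly
halves the across-array AUC dispersion relative to TBW; strongly planted
sites (shift 2) are recovered by the window test under every method
except Peng; and the mixture fit recovers the enriched fraction.

### What the generator does not model

No DNA sequences or GC content (so the documented GC-coupled LOWESS bias
on real MeDIP data is out of reach), no spatial slide layout or scanner
saturation, no probe-level cross-hybridization structure, strandless
probes. Passing tests therefore show that the methods behave as claimed
under the stated statistical structure, not that any given real dataset
has that structure.

## Numerical choices

* Log base 2 throughout; MA inversion red = 2^(A+M/2), green = 2^(A−M/2)
  round-trips to <1e-10 relative error.
* Non-positive raw intensities are rejected at read time; an explicit
  `floor_at` argument floors them instead (default suggestion: 0.5
  fluorescence units).
* Coordinates: 0-based half-open internally and in BED; GFF tracks are
  1-based inclusive; pair-file POSITION is treated as a 1-based start.
* statsmodels' C `lowess` with `delta` = 1% of the A-range keeps the
  local regression O(n) at 40k probes.
* Quantile tie handling averages the assigned scores over tied values,
  keeping the map deterministic and idempotent (to 1e-12 on tie-free
  data).
* EM tolerance 1e-8 on the relative log-likelihood change, max 500
  iterations; biweight c = 5, tol 1e-6, max 50 iterations, MAD frozen at
  the initial median.
* The VSN-style outer loop stops when the retained set repeats or the
  objective changes by <1e-8 relative; calibration parameters are bounded
  (offsets within ±2 data ranges, log-scales within ±8 of their init).

## Problem sizes

The shipped study sizes are those the reports use: 20 replicates of the
medip-like preset (8 arrays × 40k probes) for the method comparison,
n = 10,000 for mixture recovery, 20 × 2,000 tiling probes for the null
calibration of the window test, and 20 replicates with five planted
1-kb sites (shift 2.0) for recovery. A full comparison run — simulation,
all six methods, separation report and enrichment — takes a few seconds
per replicate on one CPU.

## Known limitations

* The VSN-style estimator is a simplified calibrated-glog fit; it shares
  the model class and failure mode of reference variance stabilization
  (affine calibration + glog under a majority-invariance assumption) but
  not its exact parameter estimates.
* Peng's rotation uses a total-least-squares slope; the method's original
  description leaves the slope estimator open, so the angle is always
  recorded in diagnostics for auditability.
* Window p-values are not corrected for multiplicity, matching common
  practice for this test; at alpha 0.05 a handful of spurious one-probe
  regions per 40k-probe array is expected and visible in the region
  counts.
* Normalization is applied to a whole replicate set; multi-condition
  designs (normalize per condition vs whole study) are the caller's
  responsibility.
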