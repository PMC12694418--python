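# Methods

This note documents the models, parameter choices and numerical conventions
behind `cytomorph`, and what the synthetic-data tests do and do not
demonstrate about real cytometry data.

## Gating model

Events pass four deterministic stages, with per-stage removal counts kept
for audit: (1) raw FL1 below the acquisition threshold (default 500, the
instrument cutoff used to exclude the background-noise floor); (2)
non-positive values on any of SSC/FL1/FSC, which cannot be
log-transformed (possible in area parameters; counted separately);
(3) log10 transform, then removal outside the single common polygon gate in
the log10(SSC)–log10(FL1) plane; (4) removal inside optional exclusion
polygons in log10(FL1)–log10(FL2/FL3) planes (photosynthetic picoplankton).
Conventions: log base 10 (cytometry decades); polygon membership is
boundary-inclusive and delegated to shapely (equivalent to even-odd ray
casting for the simple polygons we require); the shipped default gate is a
rectangle spanning the full decades, because a meaningful gate is
instrument- and study-specific and must be supplied by the user; a
configurable floor of 100 surviving events guards covariance stability.
Whether height (-H) or area (-A) parameters are analyzed is left to the
user's channel map.

## Ellipsoid geometry

The critical value is always computed from the chi-square quantile at the
requested confidence (0.90 → 6.251 with 3 df), never hard-coded, so other
confidence levels are available. The sample covariance uses the n−1
denominator; eigenvalues below 1e−12 are clipped to zero.

Attributing eigenvalues of a non-diagonal covariance to named channel axes
is ill-defined in general. The default rule is a bijective dominant-loading
assignment — eigenvalues in descending order claim the unused axis where
their eigenvector loads most heavily, ties broken by channel order — which
reduces exactly to the per-channel variances when the covariance is
diagonal and is deterministic otherwise. A `mode="diagonal"` switch skips
the eigen step and uses raw channel variances, for sensitivity analysis;
the two modes agree closely for the weakly-correlated clouds typical of
stained bacterioplankton.

Eccentricity with a fully collapsed minor axis returns 1.0 with a
degeneracy flag rather than raising, so batch pipelines continue; equal
axes give exactly 0.

## Type II slopes

The major-axis slope is the closed-form minimizer of summed squared
perpendicular distances,
β = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy),
evaluated in a rationalized form when s_xx > s_yy to avoid cancellation as
s_xy → 0. Degenerate cases are flagged rather than silently numeric:
`isotropic` (s_xy = 0, equal variances: no preferred axis), `zero`
(s_xy = 0, variance concentrated in x), `vertical` (s_xy = 0, variance in
y). Signed slopes are reported because the sign carries the cloud's
orientation; users wanting magnitudes can take absolute values downstream.

## Population counting

The detector is a deliberately transparent, fully parameterized version of
density-peak counting: (i) over-segment with k-means (k-means++, 10
restarts, fixed seed) at K₀ = min(⌈√(n/50)⌉, 15); (ii) estimate a smoothed
density on a 128×128 grid padded 5% beyond the data range — a binned
histogram convolved with a Gaussian kernel, bandwidth per axis by
Silverman's two-dimensional rule h = σ·n^(−1/6); (iii) repeatedly merge the
closest centroid pair whose connecting density profile (25 samples) has no
valley deeper than `merge_ratio` (0.7) times the lower of the two centroid
densities; (iv) drop populations below 1% mass, reassigning their events to
the nearest survivor. All parameters live in `PeakParams`. The procedure is
deterministic under a fixed seed; on well-separated mixtures it agrees with
a direct local-maxima count on the same smoothed grid (the oracle used in
tests). On the study generator's defaults it recovers the true component
count in roughly 90% of samples; overlapping populations (≲ 3 pooled SDs
apart) merge, as they would under any density criterion.

## Replicate QC

The F-test compares the variance of log10 FL1 between duplicates — the
channel with the acquisition threshold and the dominant biological signal —
as a single primary test to avoid multiplicity; testing all three channels
(fail if any rejects) is available via configuration. The statistic is the
larger-over-smaller variance ratio, with two-sided p = min(1, 2·P(F ≥ f)).
Event-level homogeneity is tested (not metric-level, which would need more
replicates than duplicates provide). Averaged population counts are kept
fractional for continuous analyses, with a half-up-rounded integer
companion for categorical use.

## Classification

Bin boundaries are middle-bin-inclusive everywhere (V of exactly 2.5 or
3.5 is medium; TP of 10 or 35 µg/L is mesotrophic; d-excess of 0 or −10 is
intermediate), and H = W (within 1e−9) gets an explicit `spherical-tie`
label: real data rarely hits boundaries, but the rules must be total and
deterministic. The heterogeneity rule extends monotonically past three
populations (any count ≥ 2 is complex). Elongation classes from
eccentricity use configurable breakpoints {0.3, 0.6, 0.9}; these are
placeholders for a qualitative notion, not established cutoffs.

## Multivariate stage

Both variable blocks are 0–1 normalized (constant columns map to zero and
are flagged). Collinearity screening uses Spearman correlation with
average ranks: while any retained pair has |r| ≥ 0.6, the pair with the
largest |r| is found and the member with the larger mean |r| against all
retained variables is dropped (ties drop the later variable in input
order) — a deterministic rule whose fixed point never contains an
offending pair. PCA is a column-centered SVD with component signs fixed by
making the largest-magnitude loading positive. PCoA Gower-centers −½d²,
takes coordinates from positive eigenvalues only, and normalizes relative
eigenvalues over the positive part; no Cailliez/Lingoes correction is
applied. PERMANOVA uses Anderson's sums-of-squared-distances formulation
with a seeded permutation p-value of the form (1 + #extreme)/(1 + n_perm);
999 permutations by default. PLS2 (NIPALS, via scikit-learn on blocks
z-standardized internally, so coefficients are in standardized units) uses
2 components for the headline outputs, configurable upward; VIP is the
standard Y-variance-weighted squared-weight form, so ΣVIP² equals the
number of predictors, and predictor selection at VIP ≥ 0.8 triggers a
single refit, not an iteration to a fixed point.

## Synthetic data

Clouds are mixtures of trivariate Gaussians in log10 space (log-normal in
raw units), which makes the true ellipsoid axes 2√(6.251·λ) analytic. The
instrument-noise floor is a uniform box lying fully below the raw FL1
threshold (log10 FL1 in [1.8, 2.65] against a cutoff of log10 500 ≈ 2.70),
so the acquisition stage removes it as it would on the instrument.
Defaults emulate an oligo-to-eutrophic lake survey: 20 000 events per
replicate (mid-range of typical acquisitions), duplicates per sample,
whole-cloud log variances (0.10, 0.14, 0.09) sized so ellipsoid volumes
straddle the small/medium/large bins, and two standardized latent
gradients — evaporation and trophic status — that (a) load linearly onto
18 named environmental covariates (d-excess negatively on evaporation; TP
log-linearly on trophic state) and (b) deform the clouds: both gradients
multiply the FL1 variance (taller ellipsoids), trophic state shifts the
SSC centroid, and a logistic model raises the probability of a second
(rarely third) high-fluorescence population from a baseline of roughly
20%, with tighter per-population spreads so the peaks are separated by
several pooled SDs, as in real multi-population cytograms.

What the generator does **not** emulate: spectral spillover and
compensation, doublets, instrument drift within a run, day-to-day batch
effects, non-Gaussian within-population skew, and correlated
replicate-to-replicate variation. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
robustness to every instrument artifact.

## Problem sizes and determinism

Monte-Carlo checks use 10⁵ points (ellipsoid containment, isotropic
eigenvalues), 10⁴-event clouds (axis-length recovery within 5%), 100-seed
replicate simulations (PLS sign recovery), 200 null datasets with 199
permutations each (PERMANOVA type-I calibration), and 1000 replicate pairs
(F-test rejection rate) — sizes chosen to keep the full suite in the tens
of seconds while leaving comfortable statistical margins. Every stochastic
stage takes an explicit seed; the pipeline is a pure function of its
inputs and configuration, each output file carries a hash of the
analysis-relevant settings plus the seeds, and reruns are byte-identical.

## Known limitations

- The fingerprint is instrument-dependent: a more sensitive cytometer can
  resolve populations that merge on another, changing the heterogeneity
  metric (the geometric metrics are more portable).
- The dominant-loading eigenvalue attribution can switch axes
  discontinuously for clouds whose principal axes sit near 45° between
  channels; the diagonal mode is provided to quantify this sensitivity.
- The event-level F-test is sensitive to heavy-tailed contamination; gates
  should exclude background before QC.
- Bray–Curtis on 0–1 normalized metrics treats all metrics as commensurate
  abundances; alternative coefficients may be preferable when metrics have
  very different meanings.
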