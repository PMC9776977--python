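# Methods

`adcradiomics` re-implements an ADC-based radiomic analysis of prostate
lesions as a tested pipeline: local first-order feature maps over the
prostate gland, a 132-feature per-lesion signature, two-stage feature
selection, an oversampled linear-SVM classifier of clinically significant
prostate cancer (csPCa, defined as Gleason Grade group GG ≥ 3), and a
nonparametric similarity analysis across GG groups.  Because no patient
data are available, a synthetic cohort generator provides inputs with the
statistical structure the analysis assumes; this note records the model,
the parameter choices, and what the synthetic results do and do not show.

## Local feature maps

Each gland pixel receives ten first-order statistics of the ADC values in
a square window centred on it (default 9 × 9 pixels): mean, median,
kurtosis, skewness, entropy, uniformity, interquartile range (IQR),
coefficient of variation (cv), standard deviation and median absolute
deviation (MAD).  Conventions that the definitions leave open are fixed
as follows and are switchable by configuration:

* **Variance denominator** — population (`n`), the common texture-analysis
  convention (`ddof` configurable).
* **Kurtosis** — Pearson (non-excess) `m4/m2²`; a Gaussian scores 3.
  Skewness is the moment coefficient `m3/m2^1.5`.  Constant windows return
  0 (skewness) and 3 (kurtosis) by convention, logged.
* **Entropy/uniformity binning** — 32 equal-width bins spanning the
  gland-wide intensity range of the image, shared by every window so that
  windows are mutually comparable.  Bin count is a config key.
* **Percentiles** — linear interpolation between closest ranks.
* **Window support** — a map pixel is defined only where at least 50 % of
  its window lies inside the gland (`min_support`); windows use only
  in-gland pixels.  The boundary-handling rule is this package's choice.
* **cv of a zero-mean window** — 0, logged (cannot occur for positive ADC).

The engine is vectorized (one sort per window row serves all percentile
statistics); a naive double-loop implementation in the test suite serves
as the equivalence oracle (exact for mean/std/median/IQR/MAD, ≤1e-9
relative for moment and histogram statistics).

## Lesion features

Each of the ten maps is sampled at the defined pixels inside the lesion
ROI and summarised by twelve global descriptors: the same ten statistics
plus the mean and median of the *last decile*, interpreted as the
subsample at or above the 90th percentile (inclusive, ties included).
The same twelve descriptors computed on the raw ADC values inside the
lesion complete 10 × 12 + 12 = 132 features.  Entropy/uniformity
descriptors are binned over the *map's* gland-wide value range — the same
policy as the local stage — so that, for example, a lesion whose local
means cluster tightly scores high `mu-u` regardless of how wide its own
extremes are; binning over the lesion sample's own range would make the
descriptor scale-invariant and empty it of exactly the information the
signature uses.  Lesions with fewer than 4 defined pixels on any map are
excluded with a logged reason.  Multi-slice lesions pool their pixel
samples before the descriptors (per-slice rows are available by option).

Feature names are `<base>-<descriptor>` with map bases
mu, med, k, s, e, u, IQR, cv, sigma, MAD plus `ADC`; the published
signature's symbols map to `cv-m` (median of the local cv), `mu-u`
(uniformity of the local mean), `s-s` (skewness of the local skewness)
and `sigma-IQR` (IQR of the local standard deviation).  Unicode aliases
(cv−m, μ−u, s−s, σ−IQR) are accepted anywhere a feature row is passed.

## Feature selection

After linear min-max normalization (fitted, by default, on the full
selection cohort, reproducing the original ordering of operations; a
leakage-safe train-only mode exists and is flagged in reports), selection
runs in two stages:

1. **LASSO screen** — binomial (logistic) LASSO, 10-fold stratified CV,
   minimum-CV-deviance rule, 100-point regularization grid capped at
   C = 10² (beyond that the l1 fit is effectively unregularized and the
   solver can stall on separable data).  "Weighting each sample by the
   prior probability of its membership class" is implemented as balanced
   (inverse-class-frequency) weights — the standard intent of
   class-weighted LASSO; literal prior weighting, which would further
   down-weight the minority class, is available by option.  Note that the
   minimum-CV-error rule is *liberal*: on pure-noise data the screen is
   empty in roughly three quarters of datasets and otherwise keeps a
   handful of features (a 1-SE rule would be stricter but is not part of
   the replicated design).
2. **Exhaustive quadruple search** — one linear SVM (C = 1) per
   4-combination of the screened features; a two-sided Wilcoxon rank-sum
   test compares its decision values between classes; Holm–Bonferroni at
   family level α = 10⁻³ over *all* combinations; among significant
   combinations the winner maximises informedness (SN + SP − 1 at the
   SVM's native zero threshold), with ties broken by smaller p and then
   lexicographic names.  When class separation saturates, many
   combinations tie at the minimal p and maximal informedness, and the
   tie-break — not the planted signal — decides the winner; exact-set
   recovery of a planted quadruple is therefore not a guaranteed property,
   and the tests assert the guaranteed contract instead (significance,
   optimality, majority overlap with the planted features).

## Augmentation, split and model

The four selected (normalized) features are oversampled to 200 samples,
100 per class, by within-class pairwise linear interpolation: each
synthetic sample is `x_i + λ(x_j − x_i)` with `x_j` one of the 5 nearest
same-class neighbours and `λ ~ U[0.05, 0.95]`, so originals are retained
and never duplicated.  The underlying oversampling procedure is not
specified in detail by the source analysis; this SMOTE-like interpolation
is the package's documented reconstruction (Gaussian jitter is available
by option).  Splitting is stratified 75/25 with exact class balance
(150 train / 50 test).  Default order: split the original lesions first
and oversample the two pools independently, so no synthetic sample
straddles the split; the source-faithful augment-then-split order and a
no-augmentation ("preliminary model") mode run the identical downstream
code.  The *margin rule* assignment fits a pilot linear SVM on the full
set and forces the samples nearest its boundary into training; plain
stratified random assignment is the default.

The classifier is a linear SVM with two tuned hyperparameters, the
misclassification cost C and a kernel scale γ that divides the inputs
(equivalent to rescaling C, but kept explicit to mirror the original
two-parameter search; the stored weights fold γ in).  Both are tuned by
Gaussian-process Bayesian optimization (expected improvement, 30
evaluations by default, log-uniform 10⁻⁴..10³) inside repeated stratified
3-fold CV (100 runs by default).  Candidates whose mean validation AUC
exceeds their mean training AUC are discarded as overfitting-prone; each
run keeps its best surviving candidate refit on the whole training set;
survivors are ranked by training (AUC, informedness) and the winner's
decision values are calibrated to a radiomic score in (0, 1) with a
binomial-logit (Platt sigmoid) fit.  Classification thresholds the score
at 0.5.  Reports round percentages to integers and I/AUC to two decimals;
the AUC 95 % CI is a stratified bootstrap (2000 replicates) by default,
DeLong by option.

The published four-feature signature
`g(x) = −0.04 + 1.67·cv-m + 0.96·mu-u + 0.22·s-s − 1.12·sigma-IQR`
is shipped as data and can be evaluated on any normalized feature row.
(The source's printed training PPV/NPV differ by one point from the
values its own printed confusion counts imply — 64/74 = 86 %,
65/76 = 86 % — a rounding inconsistency in the source; this package
reports the arithmetic truth.)

## Similarity analysis

Radiomic scores (decision values on the original lesions) are compared
across GG groups: Kruskal–Wallis omnibus over GG1/GG2/GG≥3 (and over
GG3/GG4/GG5, the presumed reading of the within-high-grade comparison),
one-tail Wilcoxon rank-sum pairwise tests under the alternative that the
higher-GG group scores higher (matching the monotone-median claim being
replicated), and the Ansari–Bradley dispersion test after per-group median
removal (α 0.05).  Mid-ranks with tie corrections are used throughout;
rank-sum p-values are exact for combined n ≤ 16 without ties.  All three
tests are backed by scipy and verified in the suite against exact
enumeration (rank-sum, Kruskal–Wallis) and hand-computed Ansari–Bradley
scores.

## Synthetic cohort generator

The generator emulates the cohort the analysis was designed for: 102
patients / 117 lesions with GG counts 25/36/21/23/12 (61 GG < 3,
56 GG ≥ 3), elliptical glands (default 40 × 32-pixel radii in a 112 × 112
grid at 0.78 mm spacing) and elliptical lesions with per-class lognormal
pixel areas (medians 98 / 113 px, clipped to [8, 1655]) — high-grade
lesions run larger, as in the emulated cohort.  Up to two
non-overlapping lesions share a patient; larger lesions get their own.

Tissue texture is a **two-level Gaussian random field**: the local mean
ADC is a smooth surface (amplitude `between_sigma`, correlation scale
`unit_scale` — the "unit" size of the tissue patchwork) and pixels add
Gaussian noise whose standard deviation lies between `within_sigma`
bounds, varying smoothly from unit to unit (`sigma_mode="field"`, the
default; a `"region"` variant draws one level per lesion instead).
Defaults (ADC units of 10⁻⁶ mm²/s):

| tissue | mean | between σ | within σ | unit scale |
|---|---|---|---|---|
| gland background | 950 | 80 | 60–100 | 9 px |
| GG < 3 lesion | 920 | 190 | 40–100 | 14 px |
| GG ≥ 3 lesion | 880 | 25 | 120–180 | 9 px |

These choices encode the class narrative: low-grade tumours are a
patchwork of units with differing mean ADC (large between-unit spread)
and modest within-unit noise; high-grade tumours fill their units, so
local means are uniform while within-unit variance is high and spatially
homogeneous.  GG1 and GG2 draw from one distribution, as do GG3/4/5,
giving the similarity analysis a built-in negative control.  Two non-obvious choices deserve
notice:

* **Units larger than the window for low-grade tissue.**  If the unit
  scale equalled the 9-pixel analysis window, nearly every window would
  straddle unit boundaries and between-unit mean heterogeneity would be
  statistically indistinguishable from within-unit variance at the window
  scale; the low-grade unit scale therefore exceeds the window (smooth
  correlated fields rather than hard tiles, so the decomposition is clean
  at every lesion size).
* **Matched total spread, different decomposition.**  The classes place
  similar total variance at opposite levels (between vs within units), so
  plain mean-ADC or whole-lesion dispersion is a much weaker separator
  than the *local* map features, and the lesion-background contrast is
  kept moderate so boundary windows do not drown the within-lesion
  texture.

The generator declares which feature families its class structure drives
(`PLANTED_DISPERSION_FEATURES`, `PLANTED_MEAN_UNIFORMITY_FEATURES`): the
recovery tests check that selection lands in those families, not on two
specific names, because with 132 correlated features the maximum-
informedness winner among thousands of near-tied combinations is not
name-stable — an instability the original analysis also hints at (88
significant quadruples, one winner).  The direction of `s-s` (skewness of
the local skewness) is left free: it is the signature's weakest
coefficient and no robust generating mechanism for its sign follows from
the class narrative.

A `separation` knob linearly interpolates the high-grade texture toward
the low-grade one (0 ⇒ identical classes); the suite uses it as a
negative control (downstream AUC ≈ 0.5 when textures *and* size
distributions are equalised) and for a monotonicity check.  Noise is
Gaussian by default; a Rician option exists.  No anatomical realism is
attempted — glands and lesions are ellipses, there is no MRI physics —
so passing tests demonstrate that the pipeline recovers the *statistical*
structure it assumes, not performance on real prostate MRI.

## Problem sizes used by the test suite

Unit tests run on 20 × 20 images and a 42-lesion scaled-down cohort; the
pattern-recovery suite runs the full default 117-lesion cohort for 20
fixed seeds with training scaled to 3 CV runs × 8 optimizer evaluations
and the screen truncated to its 17 strongest features (the scale of the
screened subset in the emulated analysis).  The default configuration
(100 runs × 30 evaluations, untruncated screen) is the library default.

## Known limitations

* The oversampling procedure and the margin-rule split are documented
  reconstructions of under-specified steps; both are config-switchable.
* Holm–Bonferroni over all C(k, 4) combinations is extremely strict for
  small cohorts (with ~30 lesions no combination can reach the corrected
  10⁻³ level); the exhaustive search then aborts by design.
* The synthetic cohort is more separable than a clinical one; headline
  AUCs near 1.0 on it say nothing about clinical performance.
* Feature separation and cross-lesion score diversity trade off in the
  generator: the default field-mode noise keeps every high-grade lesion
  near one effective noise level, which makes the planted features
  cleanly recoverable but leaves high-grade score variance somewhat
  tighter than low-grade — so the Ansari–Bradley comparability of score
  dispersions across GG1/GG2/GG3 holds in roughly 70 % of synthetic
  cohorts rather than always.  The `sigma_mode="region"` variant widens
  high-grade diversity and restores dispersion comparability at the cost
  of weaker, less sign-stable feature effects.  A single parameterization
  reproducing both properties in nearly every cohort was not found; the
  emulated study's own data (moderate informedness 0.68 *and* comparable
  variances) sit inside this trade-off.
* 2D only; multi-slice lesions are pooled, not modelled in 3D.
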