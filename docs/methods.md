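# Methods

This note records the models and procedures implemented in `rccpath`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Tiling and background filtering

Slides are tiled on a regular grid with 0-based, half-open pixel bounds
`[x, x + T)`, row-major ordering, tile size `T` (default 512 px) and stride
`T·(1 − overlap)` (default overlap 0.5).  Partial tiles at the right/bottom
edges are dropped rather than padded: with 50% overlap the uncovered border
is at most one stride wide, and padding would manufacture pixels the
scorer was never meant to see.

The background rule reads: a patch is background when at least a fraction
`f` (default 0.5) of its pixels have mean-over-RGB intensity strictly above
a threshold (default 210).  The phrase "mean intensity of 50% pixel values"
admits a second reading — the mean of the brightest half of the pixels
exceeding the threshold — which is implemented behind
`is_background(mode="brightest_mean")`.  The fraction-above reading is the
default because it is monotone in the white-pixel fraction and therefore
easier to reason about; on slides with clearly bimodal background/tissue
intensity the two rules agree.

## Patch scorer

The scorer is a behavioral contract: `score(patches)` returns a probability
vector per patch and `embed(patches)` a fixed-dimension penultimate
representation.  The bundled reference backbone is a single-hidden-layer
perceptron over block-averaged, per-channel-standardized pixels
(standardization statistics from the training fold only), trained by SGD
with mini-batches, epoch-wise validation, early stopping after `patience`
epochs without improvement (default 5, max 40 epochs), and restoration of
the best-validation state.  Its hidden layer (default width 512) serves as
the embedding.  This backbone trains in seconds on one CPU and is the one
exercised by the test suite; heavier convolutional backbones can be
registered under the same contract, and the default configuration carries
the fine-tuning hyperparameters typical for them (224-px inputs, batch
128, learning rate 1e-5).

Splits are made at slide level, stratified by class with largest-remainder
rounding of the 70/15/15 fractions.  Patch-level splitting would leak
near-duplicates across folds because adjacent patches share half their
pixels.

Class imbalance has two remedies.  Minority augmentation samples source
patches with replacement and applies, each independently with probability
0.5: a vertical flip, a rotation uniform in [−25°, +25°] with
reflection-filled corners, and additive Gaussian pixel noise.  The noise
standard deviation is 10 intensity units (clipped to [0, 255]) — the noise
model is otherwise unspecified, and Gaussian pixel noise is the common
default.  Reflection filling avoids white corners that would trip the
background filter.  The second remedy is inverse-class-frequency sample
weights, normalized to sum to one, under which the expected class shares of
a weighted draw are uniform.

## DAG-SVM

Each unordered class pair gets one linear soft-margin SVM (regularization
constant C, default 1.0) fit only on the samples of those two classes.
Classes are ordered lexicographically by default; decision-DAG results are
only weakly sensitive to the ordering, and fixing it makes runs
reproducible.  Prediction keeps the ordered candidate list and repeatedly
evaluates the (first, last) pair, eliminating the loser — exactly N−1
evaluations.  A margin of exactly zero eliminates the higher-indexed class;
this is a measure-zero event needing only a deterministic convention.

A DAG emits only a label, so threshold metrics use one-vs-one margin
voting: each class is scored by the sum of its signed pairwise margins.
AUC is the rank-based (Mann–Whitney) statistic with ties counted half;
micro-averaging pools all one-vs-rest decisions, macro-averaging takes the
unweighted mean of per-class AUCs and skips classes absent from the truth.

## Heatmaps, masks, morphometry

Overlapping patch probabilities are combined by per-pixel averaging —
order-independent and idempotent under patch duplication, which matters
because a 50%-overlap grid covers interior pixels four times.  Heatmaps are
materialized at a configurable downsample factor (default 8) to bound
memory on gigapixel slides; a downsampled cell is covered by a patch when
its representative full-resolution pixel (top-left corner of the cell)
falls inside the patch footprint.  Masks, component areas and all shape
features are computed at that one scale, so ratio features and the
survival stage are scale-consistent.

High-probability masking is strict (`p > 0.95`), matching the "greater
than" convention, and the pipeline additionally drops mask cells whose
representative pixel is brighter than the background threshold: patch
probabilities describe tissue, and without this restriction patches
straddling the tissue boundary paint background pixels tumor-red.
Components are labeled with 8-connectivity (diagonal touches merge, which
matches the visual continuity of tumor regions); every component smaller
than one third of the largest ("main") region is removed.  The cleanup is
idempotent and monotone in the probability threshold.

Region shape features come from the standard region-properties toolbox:
pixel-count area, hole-filled area, convex-hull area, axes and
eccentricity of the second-moment-matched ellipse, and solidity.
Perimeter uses the Crofton (4-direction) estimator, which lands within
~0.7% of 2πr on a rasterized r=50 disk; weighted boundary-step counting
was rejected because it overestimates circle perimeters by ~4%, outside
the accuracy the tests demand.  The slide-level roster is the
"total + main region" scheme: seven totals summed over retained components
(area, convex area, filled area, perimeter, major axis, minor axis, and
perimeter/area computed from the summed numerator and denominator), the
same seven for the main region, plus main-region eccentricity — 15
canonical features.  Solidity and perimeter²/area are also emitted but
flagged non-canonical, since published rosters vary; the canonical subset
is configurable.  Patient-level features are unweighted means over the
patient's usable slides; slides with empty cleaned masks are excluded with
a warning.

### Nuclei segmentation

Nuclei are segmented on the mean-RGB channel by hierarchical two-level
Otsu thresholding: the first threshold separates bright background from
stained tissue, and the darker stratum is re-thresholded once to isolate
the basophilic (nucleus) stratum.  The refinement is accepted adaptively,
with no trained parameters, only when (a) the dark stratum is strongly
bimodal — the candidate split must explain at least 75% of the stratum's
variance, roughly the value attained by two well-separated modes and well
above the ~64% a single Gaussian can reach — and (b) the refined nucleus
sub-stratum is a minority of the stratum, since nuclei are sparse within
tissue.  Without condition (b) the refinement erodes nucleus interiors on
images where nuclei are the only dark objects.  Components below a minimum
area (default 15 px at 40x) are removed.  The segmenter is pluggable: any
callable from an RGB patch to a label mask can replace it, so the survival
stage does not depend on this particular algorithm.  Per-nucleus features
are summed into seven totals (area, convex area, filled area, perimeter,
major axis, minor axis, eccentricity); the seventh (eccentricity) is an
assumption, as six totals are the commonly reported significant set.

## Survival analysis

Event model: Cox proportional hazards, h(t|x) = h₀(t)·exp(xᵀβ).  The
penalized fit maximizes the Breslow partial likelihood minus λ‖β‖₁ (mean
log-likelihood scaling, the glmnet convention) by iteratively reweighted
cyclic coordinate descent with warm starts along a geometric penalty path
(12 values from λ_max down to 0.05·λ_max by default).  Features are
standardized internally; coefficients are returned on the original scale.
The curvature weight uses the per-sample cumulative-hazard term μ_i, the
standard diagonal majorization.  λ is selected by 10-fold cross-validation
of the Verweij–van Houwelingen partial-likelihood deviance
−2[l_full(β₋k) − l_train(β₋k)].  The solver is validated against lifelines
(unpenalized limit) and a glmnet-family coxnet implementation (penalized
path) in the test suite; the hot coordinate-descent kernel is JIT-compiled
because the nested cross-validation below performs thousands of fits.

Kaplan–Meier and log-rank are implemented directly and oracle-tested: the
product-limit estimator Ŝ(t) = Π_{t_j ≤ t}(1 − d_j/n_j), and the two-group
log-rank statistic (O − E)²/V with the usual hypergeometric variance term,
referred to χ²(1).

Risk stratification follows a two-level cross-validation.  Outer loop:
each patient is left out in turn; a lasso-Cox model is fit on the
remaining n−1 patients with the penalty chosen by the inner 10-fold CV on
those patients only; the held-out patient is assigned high risk iff their
linear predictor strictly exceeds the median training risk index (ties go
to low risk — deterministic and conservative).  The loop asserts that the
left-out patient is absent from every training fit, and a test verifies
that perturbing a patient's outcome cannot change their own assignment.
After all n folds, the assembled groups are compared by log-rank, and a
group-contrast hazard ratio with Wald 95% CI is fit on the high/low
indicator (hazard ratios are reported as group contrasts and labeled as
such).  Per-feature risk indices use the identical procedure with a single
feature — for one standardized feature the lasso reduces to
soft-thresholded univariate Cox — so univariate and integrative analyses
share one code path.  Features with univariate log-rank p < 0.05 enter the
integrative model; screen p-values are reported raw (a Benjamini–Hochberg
flag is available downstream).  The one-off multivariate Cox report (risk
index plus age, gender, stage, grade) is delegated to lifelines after
zero-variance and collinearity checks.

### Known limitation: optimism of the naive log-rank p on CV groups

The log-rank p-value computed on cross-validation-assembled groups is
anti-conservative: each patient's group label depends on the other
patients' outcomes, so the labels are correlated with the outcomes being
tested and the χ²(1) reference understates the null variance.  On
pure-noise features the measured type-I error at nominal α = 0.05 is
roughly 0.12–0.20 (the package's simulations reproduce this with both the
lasso-Cox path and an independent unpenalized re-implementation of the
same loop, while a fixed outcome-independent split shows the nominal
rate).  This is a property of the protocol itself, faithfully implemented
here; when calibrated significance statements are needed, the p-value
should be referred to a permutation distribution (re-running the full
two-level CV on outcome-permuted data) rather than χ².

## Synthetic data: what it emulates, what it does not

Slides: near-white background (strictly above intensity 210, so the
background filter separates it by construction), a central textured tissue
block with class-specific base colors, Gaussian pixel noise and dark
elliptical blobs; the tumor texture occupies a known pixel mask.  Nuclei
images: non-overlapping anti-aliased dark ellipses placed by rejection
sampling, with analytic ground truth (area πab, axes 2a, 2b); tests use
tolerances because rasterization noise is unavoidable.  Embedding
clusters: spherical unit-variance Gaussians at mutually equidistant
centers, with separation measured in within-class standard deviations.
Cohorts: standard-normal features, exponential event times with hazard
h₀·exp(xᵀβ), and independent exponential censoring whose rate is
calibrated from the mean cohort hazard to hit the requested censored
fraction in expectation.

The demo study plants a recoverable image–survival association: one latent
driver per patient scales both the slide's tumor fraction and the
patient's hazard (log-hazard coefficient 1.0, 30% censoring, 48 patients —
large enough for clear log-rank power on the planted effect, small enough
to keep the full study around a minute).

None of this emulates stain variation, blur or scanner artifacts, textures
learned from real H&E, overlapping nuclei, or non-proportional hazards.
Passing tests therefore demonstrate that the pipeline's machinery is
correct (oracle-exact rules, analytic geometry, parameter recovery), not
that any particular accuracy transfers to real slides.

## Problem sizes used in tests

The suite runs on one CPU in roughly 10–15 minutes: demo slides are
256 px with 32-px tiles and a 16-px scorer input; survival power checks
use n = 200 patients × 20 replicates and the null calibration n = 50 ×
200 replicates (the measured type-I inflation above is size-invariant, so
the smaller null cohorts do not change that conclusion); geometry checks
use disks up to r = 80 and 20-nucleus scenes at 512².
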