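# Methods

This note records the models, conventions, and design choices behind
`bfmorph`, in enough detail to reproduce every number the package computes.

## Synthetic image model

A field is a 16-bit grayscale pair (bright-field + nuclear channel),
1024×1024 by default, holding cells on a jittered grid whose pitch exceeds
four cell radii so nucleus boxes and crops never overlap. Each cell is a
disk of radius 40 px (conventional, since no magnification-to-pixel scale
is assumed); the bright-field signal is i.i.d. Gaussian background noise
(mean 1000, SD 6 gray levels) plus k ~ Poisson(rate) darker filled
ellipses inside the disk. Clump areas are lognormal (median 45 px, log-SD
0.35 for wild type), orientations uniform, and the major/minor axis ratio
is a genotype parameter. Each clump's depth is `darkness × U(0.6, 1.4)`:
depth diversity matters, because with a single uniform darkness every
threshold above the clump level selects the same pixel set, the per-τ
features collapse into exact duplicates, and the lasso's choice among them
becomes arbitrary. Clumps are placed by rejection sampling with a minimum
boundary gap of 3 px (so 8-connected labeling never merges them) and a
minimum rasterized area of 5 px (so the extractor's area filter never
deletes them); draws that cannot be placed are resampled up to 60 times.
The nuclear channel holds one Gaussian blob per cell (σ = 8 px, amplitude
20000 over a background of 100 ± 5), deliberately easy for a classical
detector so that detection is never the limiting stage.

The two clones of a genotype differ by ±0.15 on the clump rate — the
smallest perturbation that makes clone pooling meaningful. Clone-adjusted
rates are clamped at zero.

**Default genotype panel.** Wild type plus eight knockouts in four paralog
pairs, each pair perturbing one clump property in a shared direction with
slightly different magnitudes: PSMA2/PSMA7 raise the count rate (4.7/5.0
vs 3.0); PSMB5/PSMB6 enlarge clumps while lowering the rate so total clump
area is roughly conserved (log-area +0.22/+0.30, rate 2.4/2.2) — this
keeps their profile direction distinguishable from the count pair's;
PSME1/PSME2 elongate clumps (axis ratio 1.6/1.7 vs 1.3); UBQLN1/UBQLN2
deepen them (darkness 68/72 vs 60). Effect sizes are calibrated so that
per-mutant nested-CV AUC falls in roughly 0.6–0.75 — the subtle regime
this kind of analysis targets — rather than at ceiling.

**What the generator does not emulate:** optics (PSF, shading, defocus),
cell boundaries visible in BF, touching cells, debris, plate or batch
effects, and any correlation between features beyond what the clump
process induces. Tests passing on this generator therefore demonstrate
that the pipeline's statistics behave correctly under its own assumptions,
not that a given real dataset is discriminable.

**Truth-matched clump counting.** The generator offers a QC quantity: the
clump count at the threshold *matched* to the planted contrast, i.e. the
absolute cut `background − shallowest depth / 2` expressed as a τ of the
crop's min–max range and passed through the ordinary binarize + label
machinery. For a cell that received zero clumps the matched cut falls
below the crop minimum — there is no planted contrast to threshold at —
and the matched count is defined as 0. On probe conditions (rate 3,
darkness 60, noise SD 2) the matched count equals the planted count for
every one of 500 seeded cells.

## Feature schema (296 values)

Eight thresholds τ ∈ {0.1, …, 0.8} of the per-crop min–max range (per-crop
normalization makes the features illumination-invariant). Per τ: 21 clump
statistics (count; total/mean/SD/min/max/median area; mean/SD/min/max
perimeter; mean/SD/min/max noncircularity; mean/max equivalent diameter;
clump area fraction; count per kilopixel; mean/max normalized centroid
distance from crop center) and 3 whole-mask measures (area, perimeter,
thinness) — 24 × 8 = 192; across-τ mean and SD of each — 48; intensity
block of 16 distribution statistics (mean, SD, skewness, excess kurtosis,
min, max, deciles d10–d90, interdecile range) plus a 12-bin normalized
histogram — 28; the same 28 for the gradient magnitude (central
differences) — 28. Total 296.

Conventions, all chosen for exact reproducibility: the perimeter is the
count of exposed pixel edges (city-block boundary); noncircularity is
`1 − 4πA/P²` clamped below at 0 and thinness its complement; clumps are
8-connected components of `pixel < min + τ·range` with area ≥ 5 px;
empty clump sets contribute zeros (never missing values); an SD over
fewer than two items is 0; skewness/kurtosis of a constant crop are 0;
a constant crop yields an all-zero threshold family with a warning. The
schema (names, order, hash) is frozen in `FeatureConfig` and serialized
with every feature table.

The τ values, and whether "size" means area or equivalent diameter, are
conventions of this package (both are in the schema); the dimensionality
and the three named across-τ features are its fixed anchors.

Image pre-filters (`blur`, `edge_enhance`, `sharpen`) are fixed
convolution kernels — the classic PIL constants, normalized to unit sum —
applied with reflected borders.

## Preprocessing

Reference statistics (mean, SD with denominator n−1) come from the raw
wild-type population; all populations, including wild type, are then
standardized by them; outlier handling runs per population; clone tables
are pooled last. Zero-variance reference features standardize to 0, are
flagged, and never trigger outlier flags. The default outlier policy drops
any cell carrying |z| > 3 in at least one feature. At 296 approximately
independent features this removes ≈ 1 − (1 − 0.0027)²⁹⁶ ≈ 55% of
perfectly Gaussian cells — an intended, documented consequence of reading
"remove outliers" as complete-case row removal; the `clip` policy
(truncate at ±3) is provided for workflows that cannot afford it.

## Discriminative model

The classifier is logistic regression with an L1 penalty on the
coefficients and an unpenalized intercept, minimizing the penalized mean
deviance `(1/n) Σ [log(1+e^η) − yη] + λ‖β‖₁`. (A squared-error loss
around the sigmoid would be non-convex and inconsistent with reporting
posterior probabilities; the deviance objective is the standard
lasso-logistic formulation, as in glmnet.) The solver is glmnet-style: IRLS quadratic approximation with
cyclic coordinate descent on the working weighted least squares, soft
thresholding at λ, warm starts down a log-spaced λ path from
`λ_max = max_j |x_jᵀ(y − ȳ)|/n` (the closed-form smallest all-zero-β
penalty), an ever-active feature set with KKT screening of inactive
features after each solve, weights clamped at 10⁻⁶, η clipped at ±30, and
step-halving backtracking so the recorded objective trace never increases.
Full fits converge to a 10⁻⁸ parameter tolerance and match an independent
Newton–Raphson (statsmodels) fit to < 10⁻⁶ at λ = 0. CV *selection* paths
run with a looser tolerance (10⁻³) and capped iterations (4 IRLS × 8
sweeps per λ): on the collinear texture features this leaves the
per-λ validation deviance curve — and hence the selected λ — unchanged
while cutting an order of magnitude of runtime; the model finally
reported is always refit at 10⁻⁶.

λ is selected on a grid of 100 values over 4 decades (package default;
scaled experiments use 50 values over 3 decades as part of their problem
size) by inner K-fold mean validation deviance. Two rules are exposed:
`"min"` (deviance minimum) and `"1se"` (largest λ within one SE of the
minimum). The library default is `"1se"`: on data with a small planted
feature set it recovers that set with high precision, where `"min"`
over-selects several-fold. The pipeline default is `"min"`: coefficient
profiles destined for clustering benefit from the denser models. Ties
in the deviance resolve toward the larger λ (sparser model).

Accuracy is nested stratified 10×10-fold CV: inner folds choose λ on each
outer-training split, the model refits on that split, and outer-test cells
produce a fold ROC (tie-grouped step curve; trapezoid AUC, equal to the
tie-corrected Mann–Whitney statistic over n₁n₀). "Selected features" of a
dataset means the nonzero coefficients of the full-data refit at the
CV-chosen λ.

Single-feature comparisons use the one-sided Mann–Whitney U test, exact by
enumeration for tie-free samples with n₁+n₂ ≤ 12 and the tie-corrected
normal approximation otherwise.

## Profiles and clustering

A mutant's morphological profile is its coefficient vector; unselected
features are exact zeros. Similarity is Pearson r between profiles (raw
coefficients, no row scaling), distance 1 − r, clustering agglomerative
complete linkage with ties broken toward the first pair in label order;
heights are non-decreasing by construction and the tree exports to Newick.

Because many texture features are near-duplicates, a single lasso refit
picks one representative per correlated group essentially at random, and
profiles of replicate experiments share little support (within-pair
Pearson r ≈ 0.1 on the synthetic panel). The pipeline therefore builds
profile rows as the average coefficient vector of 24 bootstrap refits, all
at the λ chosen once by CV on the full data: the average spreads weight
over each correlated group in proportion to selection frequency and is
stable across replicates (within-pair r ≈ 0.3–0.85; all four planted
paralog pairs monophyletic in every one of 14 validation runs at the
scaled problem size). The single-refit profile matrix remains available
(`profile_mode="refit"`, and the CLI path that clusters saved model
JSONs).

Pair-specific features follow the sign rule: coefficient > 0 in both pair
members and ≤ 0 (including unselected) in every other mutant, plus the
mirrored negative variant.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.Generator` / `SeedSequence`; identical config + seed gives
byte-identical tables, models, and manifests. The default experiment
(1024² fields, 700 cells per genotype, 10×10 CV, 100-λ grid) is sized for
a single workstation CPU; the test suite and the acceptance script run the
same code at reduced sizes chosen as their experimental conditions — 512² fields
with 9 cells each, 200–500 cells per genotype, a 40–50 value λ grid over
2.5–3 decades — which keep every statistical conclusion (calibration,
recovery, co-clustering) intact at a few seconds to a few tens of seconds
per run.

## Known limitations

- The 296-feature schema is this package's own documented construction in
  the tradition of fixed-dimension bright-field texture extractors; its
  per-feature values are not comparable to any other extractor's — only
  the analysis structure carries over.
- The nucleus detector is a classical threshold/components stand-in tuned
  to the synthetic nuclear blobs; it is not a general-purpose detector and
  will undersegment touching nuclei.
- Nucleus-box cropping with a 0.5 expansion covers most but not all of a
  synthetic cell; features are window statistics, not whole-cell
  measurements (as with any nucleus-anchored crop).
- Lasso coefficient profiles remain selection-noisy at small n even with
  bagging; pair co-clustering reliability is a statement about the default
  panel at the documented sizes.
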