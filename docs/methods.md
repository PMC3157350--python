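# Methods

This note documents the models, procedures and numerical choices behind
`facetraits`, in the order the pipeline runs them.

## Synthetic rated faces

The generator emulates a database of randomly generated, neutral, frontal
face portraits that were each rated on nine social traits on a continuous
1–9 scale.

**Shape model.** Landmarks live in a fixed 21-point template (brows, eye
corners, nose, mouth, chin, cheek/jaw contour), scaled into image
coordinates. A face's landmarks are `mean + M c`, where the columns of
`M` (42 × k, orthonormal) are shape modes and `c ~ N(0, mode_sd² I)`.
The leading modes are orthonormalized versions of interpretable
deformations — face width/height scaling, mouth widening, inter-ocular
spacing, brow raise, chin/nose lengthening, lip thickening — so that the
named measurements the trait models use genuinely vary; modes beyond
those are seeded random directions. Defaults: k = 5 modes, mode_sd = 3 px
at 64×64. Because the columns are orthonormal, the marginal SD of each
landmark coordinate is `mode_sd · ‖row‖`, which the tests check by Monte
Carlo. Out-of-bounds configurations are resampled (cap 10), keeping
generation time bounded.

**Rendering.** A deterministic 2-D parametric painter: shaded head oval,
thick-segment brows, two-layer eyes, nose wedge and nostrils, lip
ellipse, then Gaussian smoothing (σ = 0.7 px) and clipping to [0, 1].
Three per-face appearance parameters — skin, brow and lip intensity,
clipped-normal around 0.5 — modulate part contrast. Appearance is thus a
deterministic function of (landmarks, appearance parameters), and both
channels are coupled: geometry changes move rendered parts, so holistic
descriptors see structural signal too, while the appearance parameters
give the holistic channel information the landmark descriptor cannot see.

**Trait scores.** `score = clip(intercept + Σ w·feature + N(0, noise_sd²), 1, 9)`,
where features are named structural measurements (pixel units: mouth
width, inter-ocular distance, brow–eye distance, …) or appearance
parameters. Since features are in raw units, the default specs set each
intercept to `5 − Σ w·feature(template)` so ratings center on 5. Default
`noise_sd = 0.5` rating units against planted parts of roughly unit SD
gives planted R² around 0.8, a deliberately optimistic but not degenerate
rater-reliability regime. Traits share features (brow height/darkness
across the dominance-like traits; skin tone across the valence-like ones)
to give the rating matrix the low-rank correlation structure a
valence/dominance PCA expects; "competent" is intentionally weakly
modeled and should stay hard to predict. `planted_benchmark_specs()`
sharpens three traits for recovery experiments: "dominant" planted in
structure *and* appearance, "extroverted" on mouth width alone,
"frightening" on brow darkness alone (appearance-only).

**What this does not emulate.** No 3-D geometry, pose or lighting
variation, no photorealistic texture, no rater-specific biases beyond
additive Gaussian noise, no landmark annotation error. Passing tests
therefore demonstrate the *pipeline's* correctness and sensitivity under
controlled signal, not expected accuracy levels on real photographs.

## Structural descriptor

Three concatenated blocks (lengths 2P, 2P², P(P−1)/2; 1134 at P = 21):
point-to-own-mean polar differences, point-to-every-mean polar
differences, and within-face inter-point distances. Conventions, fixed so
feature indices are stable: angles are `atan2(Δy, Δx)` in image
coordinates (y down), radians in (−π, π], zero at zero radius; block 2 is
row-major in (i, j) and includes i = j; block 3 enumerates i < j
lexicographically. Block 1 is redundant with the diagonal of block 2 but
kept as an explicit component of the three-block construction. The
descriptor is invariant to joint translation of face and mean shape; it
is deliberately *not* Procrustes-aligned or scale-normalized — size and
position relative to the mean face are part of the signal. Every index
maps to its landmarks and kind, which is what the importance analysis
consumes.

Within cross-validation the mean shape is recomputed from each training
fold (and likewise the reference face and eigen-basis below): the
descriptor definition depends on data, so fold hygiene requires refitting
it per fold.

## Shape normalization and holistic descriptors

Appearance must be measured with geometry held fixed, so each image is
warped so its landmarks land on a reference configuration — the training
face minimizing summed landmark distance to the mean shape (the face
deformed least on average). The warp is piecewise-affine over a Delaunay
triangulation of the reference landmarks plus 8 fixed border anchors;
control points map exactly, and degenerate (collinear) triangles on
either side raise an error naming the triangle. A landmark-driven warp
was chosen over intensity-based registration because exact landmark
correspondences are available by construction; it is deterministic and
satisfies the same contract (structure removed, appearance kept). Warped
images are cached per (face, reference) since the reference rarely
changes between folds.

**EigenFaces:** SVD of the centered vectorized images; retain the
smallest k whose cumulative eigenvalue share reaches the variance
fraction (default 0.95); component signs fixed deterministically.
**HOG:** central-difference gradients on a replicate-padded image;
orientation folded to [0°, 180°) (unsigned); magnitude-weighted linear
interpolation between the two nearest bin centers, with centers at
`i·180/n_bins` so an axis-aligned edge falls exactly on a center; 8-px
cells, 2×2-cell blocks, 1-cell overlap, 9 bins; per-block L2
normalization with ε = 10⁻⁶ (entries nonnegative, block norms ≤ 1,
invariant to affine intensity scaling). All geometry parameters are
configurable; defaults are recorded in the run manifest.

## Classification protocol

Ratings are ranked (ties broken by sample id) and the top/bottom
⌈fraction·n⌉ become class/no-class (default one third per side; the
per-side count is capped at ⌊n/2⌋ so the sets stay disjoint at
fraction 0.5 with odd n). Discarding the middle reduces the influence of
borderline ratings. Folds are stratified; features are z-scored with
training-fold statistics (needed by the distance- and kernel-based rules
on mixed-unit features; constant features map to 0).

Bank members and their confidence semantics (larger = more class-like):

* **GentleBoost** (default 100 rounds): each round fits the
  weighted-least-squares regression stump minimizing weighted squared
  error to the ±1 labels via an O(n·d) presorted cumulative-sum search,
  adds it to the additive score F, and re-weights by `exp(−y f)`.
  Leaf values are weighted label means, so |f| ≤ 1 and the mean
  exponential loss is non-increasing (tracked and tested). Confidence:
  the margin F.
* **SVM-RBF**: C ∈ {1, 10, 100} × γ ∈ {0.1, 1, 10}·γ₀ (γ₀ the
  1/(d·Var(X)) heuristic) by stratified 3-fold grid search on the
  training fold. Confidence: decision function.
* **Tree**: cost-complexity pruning path on the training fold, α chosen
  by inner 3-fold CV (≤ 8 candidate α values; ties prefer the less
  pruned tree). Confidence: signed class-probability difference.
* **5-NN**: Euclidean; neighbor-distance ties broken by smaller training
  index (stable argsort); vote ties cannot occur at odd k. Confidence:
  share of the k neighbors voting positive.
* **Parzen + Random Subspace** (default M = 25 subspaces, ρ = 0.5):
  per-subspace two-class Gaussian kernel density classifier with
  diagonal per-feature bandwidths by Silverman's rule per class
  (σ floored at 10⁻³; log-density via logsumexp, so it stays finite in
  hundreds of dimensions where a full-covariance KDE would be singular).
  Majority vote; confidence: subspace vote share.

Mean fold accuracy is reported with half-width `t₀.₉₇₅,N−₁ · s/√N` (s the
fold-accuracy sample SD; a z multiplier is a config switch). **Known
limitation:** CV folds share samples, so this classical interval
undercovers the variability of the CV mean — under permuted labels its
empirical coverage of the 50% chance level is about 80–90%, not 95%. The
acceptance script measures this coverage; treat the intervals as
descriptive spread, not exact inference.

## Second-level analyses

Predicted-label agreement between two descriptor pipelines is the Pearson
correlation of the ±1 out-of-fold prediction vectors (equal to the phi
coefficient); out-of-fold predictions are used rather than refit-on-all
ones to keep the comparison leak-free. Constant vectors are reported as 0
with a flag. Feature–label correlation is per-column Pearson against the
±1 labels; features whose |correlation| passes a threshold (default: top
5% quantile; an absolute cut is also supported) each increment every
landmark in their provenance record — for block-2 features both i and j,
since a mean-face point is the same anatomical landmark — and counts are
normalized by their maximum. The angle/distance composition of the
selection is tallied from the same records. Trait PCA eigendecomposes the
correlation matrix of the *continuous* ratings (binarized labels are an
option); zero-variance traits are dropped and flagged, which makes
variance shares well-defined in degenerate cases. Gallery ranking sorts
by classifier confidence, ties broken by id.

## Problem sizes and determinism

Test and benchmark datasets use 64×64 images and 120–300 faces — enough
for the planted signals to be decisively recoverable while keeping the
full suite fast on a single CPU. Every random choice (shape coefficients,
appearance parameters, rater noise, fold shuffles, subspace draws,
permutations) derives from explicit integer seeds; a fixed seed makes
datasets byte-identical and experiment CSVs byte-reproducible. The run
manifest records the full configuration, so every output file is
derivable from it.
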