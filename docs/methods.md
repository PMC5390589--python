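# Methods

## Model

The feature extractor is a two-stage unsupervised convolutional cascade.
Stage s learns a bank of Vₛ eigenfilters: all overlapping s₁×s₂ patches of
the stage inputs are taken at stride 1 (valid positions only), each patch
has its own mean subtracted, and the pooled scatter matrix T Tᵀ is
eigendecomposed; the leading eigenvectors, reshaped row-major to s₁×s₂,
are the filters. The scatter matrix is conventionally scaled by
1/(N·p·V); eigenvectors are invariant to any positive rescaling, so this
constant affects only the reported eigenvalues (a property the test suite
verifies directly).

Convolution uses the correlation convention (no kernel flip), zero
padding of width ⌊s/2⌋, and per-patch mean removal at convolution time as
well, so each response is the projection of a mean-removed patch onto an
eigenfilter — consistent with the statistics the filters were learned
from, and invariant to constant intensity offsets in the map interior
(boundary patches mix in the fixed zero padding). The response passes
through tanh, then the nonlinear transformation (NT)
`a·sqrt(eps + C²) + (1−a)·softplus(C)`, which makes every map entry
strictly positive (≥ √ε when a = 1). The softplus branch uses
`logaddexp(0, C)` for stability at large |C|. The stage-2 NT consumes the
stage-2 convolution output; the cascade applies the same NT after each
convolution layer.

Pooling converts the V₁·V₂ stage-2 maps of an image into one vector:

1. **Heaviside hashing.** The V₁ binary maps sharing stage-2 filter j are
   combined pixelwise into an integer word H = Σ_k 2^(k−1 mod 256)·B_k.
   The Heaviside step is applied to the *pre-NT* map C² at threshold 0 by
   default: both NT branches are strictly positive, so thresholding the
   post-NT map at 0 would hash every pixel to the maximal word and the
   representation would collapse. This is the one genuinely open point in
   the design; an alternative `nt_centered` source (T² minus its map
   mean) is provided for experimentation.
2. **Per-map min–max rescale** of the word image to [0, 255], rounding
   half away from zero (deterministic and locale-free); a constant map
   becomes all zeros. Rescale statistics are per image and per map; a
   dataset-global rescale would leak test-set statistics.
3. **Multiscale feature analysis.** A spatial pyramid at levels 0..L with
   a 2ˡ×2ˡ cell grid per level (cell boundaries at ⌊m·r/2ˡ⌋) and a
   256-bin word histogram per cell, cells ordered level-ascending then
   row-major: G = Σ 4ˡ cells (21 at L = 2). The per-level 2ˡ×2ˡ grid is
   the standard spatial-pyramid construction and is what the
   feature-length contract 43008 = 8·21·256 requires.
4. **High dispersal** rescales each G×256 feature to Euclidean norm σ
   (the all-zero feature passes through), giving the testable invariant
   ‖f̃‖₂ = σ; a no-sqrt variant (divide by the plain sum of squares) is
   available behind the `hd_sqrt` flag but has no fixed-norm property.
5. **Local response normalization** divides each entry by
   (γ + α·Σ f̃²)^β, the sum running over the window of ⌊n/2⌋ neighboring
   maps on each side in stage-2 filter order, clipped at the ends.

Ablation flags (`use_nt`, `use_mfa`, `use_hd`, `use_lrn`) switch the four
components off individually; with all four off, the pipeline reduces to a
PCANet-style baseline of hashed histograms of length V₂·256.

## Parameters

| name | meaning | default | note |
|---|---|---|---|
| V₁, V₂ | filters per stage | 8 | 8 bits → words in [0, 255] |
| s₁×s₂ | filter size | 5×5 | odd dims required (center pixel) |
| ε | NT smoothing floor | 1e-8 | a = 1 branch floor √ε = 1e-4 |
| a | NT branch selector | 1 | smoothed absolute value |
| γ, α, β | LRN offset/scale/power | 2, 1e-4, 0.75 | |
| n | LRN window size (maps) | 5 | ⌊n/2⌋ neighbors per side |
| σ | dispersal norm | 2.238 | adopted as printed; see below |
| L | pyramid depth | 2 | G = 21 cells |

σ = 2.238 is adopted verbatim as the operating value. The grid used to
tune it, σ = 315·t/84 with t ∈ {0.59, 0.60}, yields 2.2125 or 2.25 —
neither reproduces 2.238 exactly; the grid is honored verbatim in
`default_grids()` while the fixed default stays at the printed 2.238.
The hyperparameter search grids (ε in decade steps over [1e-10, 1],
a ∈ {0,1}, γ ∈ 0..10 step 2, α in decade steps over [1e-6, 1e2],
β ∈ 0..1 step 0.25, integer n) are exhaustive by design; the search
objective is not prescribed anywhere, so the balance metric g (product
mode) on a stratified validation split of the training subset is the
default, with ties keeping the first grid point in iteration order.

## Evaluation protocol

The classifier is an L2-regularized hinge-loss linear SVM (liblinear via
scikit-learn's `LinearSVC`, dual formulation — appropriate with 315
samples and 43008 features) with per-class weights; cost C defaults to 1.
The positive class is abnormal (label 1): sensitivity = abnormal recall,
specificity = normal (minority) recall. Metrics with zero denominators
are reported as NaN (undefined), never as silent zeros, and fold
averaging is NaN-aware. The balance metric defaults to the product
SEN·SPE because the reference weight-sweep table tabulates the product
(e.g. 0.9426·0.7540 = 0.7107), despite being *named* a geometric mean;
the sqrt mode is also implemented. Folds are stratified — with only 48
minority samples, unstratified 5-fold splits can produce degenerate
folds — and each repeat reshuffles with seed + repeat index, so a
(seed, k, repeats) triple fully determines the protocol.

The filter-learning subset (default 40 normal + 44 abnormal, 26.67% of
315) is drawn once per run seed; features for the remaining images are
extracted with those learned banks, never re-fit, so no information flows
from test images into the representation.

## Synthetic data

The generator emulates what the pipeline needs from the private clinical
data — two texture-distinguishable classes on an elliptical bright
foreground at an 85:15 imbalance — and nothing more. Class 0 is the
ellipse with a smooth Gaussian-correlated base texture (correlation
length 3 px, amplitude 30 intensity units); class 1 additionally receives
Poisson-placed bright coating spots (amplitude 90, blurred σ = 0.6 px)
with expected density `contrast · spot_density` per foreground pixel.
Defaults: 48 normal + 267 abnormal 32×32 images, spot density 0.25 (a
dense, clearly visible coating, as abnormal tongue coating is to a
clinician), additive Gaussian pixel noise σ = 2, contrast 1. At
contrast 0 the class label does not enter the generative process at all,
so the two class-conditional distributions coincide exactly — the
null-case tests rely on this.

What the generator does *not* model: color, illumination variation,
segmentation artifacts, pose, or any clinically meaningful morphology.
Passing tests therefore demonstrate that the pipeline can learn planted
texture differences under the study's imbalance and sample size — not
that it reaches any particular accuracy on clinical images.

## Problem sizes and numerical choices

The end-to-end benchmark in the test suite uses the full 315-image
dataset with 2×5-fold CV (the package's CV default is 10×5; two repeats
estimate the same mean with enough precision for the behavioral
assertions). Unit tests run a reduced cascade (V₁ = V₂ = 2, 3×3 filters,
16×16 images) whose contracts are size-independent. Eigendecomposition
uses `numpy.linalg.eigh` on the symmetric scatter matrix; eigenvector
signs are fixed by making the largest-magnitude entry positive (first
index wins ties), and tied eigenvalues are ordered by the sign-fixed
lexicographic order of their vectors, so filter banks are bit-reproducible
across runs. Degenerate inputs are handled explicitly: an all-constant
training set raises a degenerate-filters error; a constant image flows
through the pipeline to a well-defined feature vector (zero interior
responses, words from the boundary ring only).

## Known limitations

- Images are processed single-channel; any color handling happens before
  the pipeline (luma conversion at load time).
- Two stages only; stride is fixed at 1; the pyramid uses non-overlapping
  cells.
- The Heaviside-source question above means the default pooling is a
  reasoned reconstruction of underspecified behavior, not a verified
  replica; both options are exposed.
- `LinearSVC`'s dual coordinate descent is deterministic only up to its
  tolerance; results are seeded and stable in practice, but byte-identical
  decision functions across library versions are not guaranteed.
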