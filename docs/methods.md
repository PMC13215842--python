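# Methods

`cytofuse` implements a complete single-cell leukocyte classification
stack: class-balancing photometric augmentation, handcrafted descriptor
extraction, deep-embedding extraction, chi-square feature fusion, a hybrid
CNN + Vision-Transformer classifier operating on pseudo-images, and an
evaluation suite.  This note records the model, its assumptions, the
numerical choices made where the design was open, and what the synthetic
test bed does and does not demonstrate.

## Synthetic image generator

Real cytomorphology collections are folders of single-cell RGB crops, one
folder per leukocyte class, with strong class imbalance (rare classes in
the tens, common classes in the thousands).  The generator emulates that
*structure*: each image is one stain-colored elliptical cell with an
interior nucleus on a uniform light background, with class-dependent
parameter ranges for cell radius, eccentricity, nucleus area fraction,
stain hue, and the spatial frequency of a multiplicative intra-cell
intensity grain.  The default fixture has four classes with counts
{60, 150, 400, 1200} at 96×96 px — a long-tailed inventory at desk scale —
and disjoint hue intervals plus graded size/shape/texture parameters, so
the classes are separable by construction.

What it does **not** emulate: nucleus lobulation, cytoplasmic granules,
multi-cell scenes, staining batch effects, focus variation, or any
realistic intra-class appearance manifold.  Passing tests therefore
demonstrate that the pipeline's stages are implemented correctly and that
the system can learn separable structure end-to-end; they say nothing
about accuracy on clinical data.

Determinism: every image's RNG stream is derived from
`(master seed, class name hash, image index)`, so datasets are
reproducible image-by-image and independent of generation order.

## S3A class balancing

Six photometric transforms emulate acquisition artifacts; parameter laws:
brightness factor α ~ U(0.85, 1.12); contrast factor β ~ U(0.85, 1.2)
applied about the image mean μ; additive Gaussian noise with σ = 5
intensity units; salt-and-pepper corruption with probability ρ = 0.002 per
polarity; 3×3 Gaussian blur; pixel dropout with probability 0.005.  Every
augmented image receives a randomly composed chain of 1–3 *distinct*
transforms (the composition length is not prescribed beyond "multiple";
1–3 keeps artifacts mild enough to preserve class semantics), with
parameters sampled per transform instance.

Balancing to a per-class target T (default 2000): classes with N_c < T
keep all originals and receive T − N_c augmentations of uniformly drawn
originals; classes with N_c ≥ T keep exactly their first T images in
lexicographic filename order (the truncation rule needs *some* canonical
order; lexicographic is stable across file systems).  Balancing is applied
to the training split only — test images never pass through augmentation.

Numerical conventions: all transforms clip to [0, 255] and round to 8-bit
after each step, keeping chains composable and file-writable.  Blur uses
reflect padding (preserves the image mean to < 1 intensity unit) and
σ = 0.8 derived from the 3×3 kernel by the usual kernel-size rule.
Stochastic transforms record their integer seed in the chain parameters,
so any augmented image is bit-exactly replayable from the manifest.

## Handcrafted descriptors (19 dimensions)

Segmentation: Otsu threshold on the ITU-R 601 luma, polarity fixed so the
cell is foreground (if ≥ 3 frame corners land in the foreground the
threshold picked the background side and the mask is inverted), then the
largest connected component.

* **Shape (4)** — area, major/minor axis of the second-moment best-fit
  ellipse, solidity (area / convex hull area), via `skimage.regionprops`.
* **Color (6)** — std of R; mean/std of HSV hue (scale [0, 1)); mean/std
  of HSV saturation; mean of CIE-Lab b\* on the signed scale (D65,
  achromatic ≈ 0).
* **Texture (7)** — luma std, skewness, kurtosis (Pearson convention: the
  raw fourth standardized moment, 3 for a Gaussian), base-2 Shannon
  entropy of the 256-bin histogram (0·log 0 ≡ 0), and GLCM contrast /
  correlation / homogeneity.  GLCM: distance 1, angles {0°, 45°, 90°,
  135°} averaged, 64 uniform gray levels, symmetric, normalized.  Constant
  images: skewness, kurtosis, and GLCM correlation are returned as 0 by
  convention.
* **Fractal (2)** — box-counting fractal dimension as the least-squares
  slope of log N_b vs log(1/b) over dyadic box sizes b ∈ {2, 4, …,
  min(H, W)/2} (the single-scale ratio −log N_b / log b is available
  behind a flag; the regression reduces to it under exact self-similar
  scaling and is far more stable on rasters), and lacunarity
  var/mean² of per-box occupancy counts over occupied boxes at b = 8
  (configurable; 8 suits 96×96 crops).

Color/texture statistics default to the whole frame: single-cell crops are
cell-dominated and the uniform background contributes a stable offset.  A
`masked` mode restricts them to the segmented cell; the GLCM stays
full-frame in either mode because co-occurrence offsets are ill-defined on
ragged masked regions.

The 19-feature composition is itself the outcome of a group-wise
random-forest importance screen over candidate pools (8 shape, 12 color,
13 texture, 2 fractal descriptors).  `rf_group_select` implements the
screen as a real procedure: one 200-tree seeded forest, mean impurity
decrease, top-k per group with ties broken by column order.  The pool
members beyond the selected nineteen are standard region/color/GLCM
descriptors (perimeter, eccentricity, extent, orientation; RGB means,
V-channel statistics, Lab-b\* std; GLCM energy/dissimilarity/ASM,
intensity mean/median/range) — a reasonable reconstruction, since only the
selected descriptors are canonical.

## Deep embeddings

The embedding contract: resize to the backbone input size (bilinear, no
aspect padding — crops are near-square), apply the backbone's canonical
normalization, run the convolutional trunk, global-average-pool the final
maps to a d-vector.  The built-in backbone is a **stub**: three seeded
He-initialized random 3×3 stride-2 convolutions with ReLU (3→8→16→32
channels, input 64×64, inputs scaled to [−1, 1]), giving d = 32.  Random
convolutional features are a classical baseline — they are informative
random projections of local image statistics — and the stub is fully
deterministic per seed with no download.  Externally trained trunks can be
plugged in as callables satisfying the same contract; the two deep arms of
the ablation use independently seeded stubs.

## Fusion and chi-square selection

Fused descriptors are column concatenations [handcrafted ‖ deep].  Columns
are MinMax-scaled to [0, 1] (constant columns map to 0 to avoid 0/0; test
rows are transformed with training statistics and clipped).  The
chi-square relevance of a non-negative continuous column uses the standard
class-conditional column-sum contingency construction (identical to
`sklearn.feature_selection.chi2`): O_jr is the column sum over class r,
E_jr the column total weighted by the class share, the statistic
Σ_r (O−E)²/E with C−1 degrees of freedom.  Selection is either all
columns with p < 0.05 or top-k by statistic (ties broken by column index);
both modes are exposed since either is defensible.  If the p-rule selects
nothing (possible at very small n), the pipeline falls back to keeping all
columns rather than training on an empty matrix.  All scaler and selector
statistics are fitted on the training split only.

## TCMA-Net classifier

Inputs are standardized feature vectors (per-column z-score with
population std fitted on training rows; constant columns → 0) spatialized
into pseudo-images: row-major fill of an m×m grid with m = ⌈√d⌉ (the
ceiling is the only reading consistent with zero-padding the tail),
zero-pad the remaining m²−d cells, bilinear resize to 32×32×1 with
pixel-centred separable weights (exact identity at d = 1024).

Architecture (defaults):

| component | value |
|---|---|
| input | 32×32×1 |
| CNN branch | 3 blocks: [conv3×3+ReLU, conv3×3+ReLU, batch norm, 2×2 max pool, dropout 0.2], filters 32→64→128; flatten; dense 256 + ReLU + dropout |
| ViT branch | 4×4 patch grid (8×8 patches), learnable linear embedding to dim 32 + learnable positional embeddings; 2 pre-norm transformer layers, 2-head self-attention, ReLU FFN of width 64; flatten; dense 256 + ReLU + dropout |
| fusion | concat (512) → dense 128 + ReLU + dropout → dense 64 + ReLU → softmax head |
| training | Adam, η = 1e−4, batch 64, categorical cross-entropy, up to 100 epochs |

Open points resolved here: no class token (the whole token sequence is
flattened); learnable rather than sinusoidal positional embeddings; FFN
width 2× the projection dim with ReLU (matching the activation used
everywhere else); 2×2 max pooling (unspecified pool size); dropout 0.2 at
every dropout site; ViT-branch dense width 256 (symmetric with the CNN
branch) and fusion widths (128, 64) — all unspecified dimensions chosen as
common defaults and fixed.  One-hot targets use lexicographic class order,
consistent with the label encoder.

The network is implemented directly in NumPy with manual
backpropagation (`cytofuse.nn`): im2col convolution, batch/layer norm,
max-pool, inverted dropout, multi-head attention, Adam.  Every layer's
backward pass is verified against central finite differences in the test
suite.  The output head is zero-initialized so the softmax starts uniform
(initial loss = ln C) and early training is stable.  All arithmetic is
float32; initialization, shuffling and dropout derive from the single
config seed, making training bit-reproducible.

## Experiment protocol and desk-scale sizes

`run_experiment`: stratified 80:20 split (per-class rounding, ≥ 1 sample
on each side where possible) → S3A balancing of the training split only →
arm features → scaling/selection fitted on train → TCMA-Net → evaluation
on the untouched test split.  Five arms: `hcf`, `densenet`, `mobilenet`
(stub-served), `hcf+mobilenet`, `hadnet` (handcrafted ‖ deep, scaled,
chi-square-selected).

`desk_experiment` fixes the package's reference problem size: the default
4-class fixture, balance target 250 per class (1000 training images) and
30 training epochs.  These sizes were chosen once as a CPU-friendly
miniature of the full protocol (which defaults to target 2000 and 100
epochs) and are used by the acceptance checks; the expectation at this
scale is that every arm learns the separable fixture well (≥ 0.90
held-out accuracy for the fused arm) and that the fused descriptor is not
worse than the handcrafted one — the qualitative ordering, not any
specific headline accuracy.

## Metrics

Confusion-matrix based accuracy, per-class and macro precision/recall/F1
(zero denominators → 0), MCC in the covariance form (reduces exactly to
the binary formula at C = 2), macro one-vs-rest ROC AUC by trapezoidal
integration (classes absent from the truth are skipped with a warning).
EAR is the misclassified fraction, so accuracy + EAR = 1 identically.
FIS is the mean absolute difference of integer-encoded labels, as
defined; note that despite its name it is a *disagreement* magnitude
(0 is best) and for C > 2 its value depends on the label encoding order —
the implementation warns in that case.  Macro averaging is used throughout
because it is the imbalance-sensitive choice.

## Known limitations

* The stub backbone is a random-projection feature extractor, not a
  pretrained network; absolute accuracies of the deep arms are not
  comparable to ImageNet-initialized trunks.
* The synthetic fixture's separability makes near-ceiling accuracy easy;
  the tests certify mechanism, not clinical performance.
* The chi-square construction treats scaled feature sums as frequencies —
  the de-facto convention for continuous features, but a modeling
  convenience rather than a sampling-theory-exact test.
* FIS inherits its encoding-order dependence by definition.
* Pure-NumPy training is CPU-bound; the default 100-epoch configuration at
  target 2000 is hours of CPU, which is why the desk-scale sizes above are
  the tested reference point.
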