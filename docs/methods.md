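# Methods

`cellquant` estimates tumor cellularity — the fraction of patch area
occupied by malignant epithelial cells, on a 37-value grid spanning
[0, 100%] — directly from H&E-stained histopathology patches, without
segmenting or classifying individual nuclei. This note records the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Pipeline

### Stain normalization

Stain mixing is linear in optical density. Images are mapped by
`OD = -log10((I + 1) / 256)`; the +1 offset keeps the logarithm finite at
I = 0 and makes the RGB↔OD round trip exact on 8-bit data. Per-image H and
E directions are estimated SVD-style: foreground pixels (OD norm > β =
0.15) are projected onto the top-2 singular plane and the stain vectors
read off at the α = 1 / 99 angular percentiles. β and α are the standard
values for this family of estimators. The vector with the larger
blue-channel loading is labelled hematoxylin; the packaged reference stain
(a unit-normalized Ruifrok-style pair, `config/reference_stain.yaml`) was
chosen so this rule is self-consistent on data synthesized from the
reference itself.

Concentrations are solved by exact two-variable nonnegative least squares
(vectorized KKT cases), rescaled by the ratio of reference to per-image
99th-percentile concentrations, and reconstructed with the reference
vectors. Degenerate patches — fewer than 100 foreground pixels, a
second-singular-value ratio below 1%, or angular spread under 2° — pass
through unchanged with a warning rather than aborting a batch, because
benign patches at cellularity 0 can be nearly unstained. The two
degeneracy thresholds separate quantization noise from genuine two-stain
clouds by about two orders of magnitude on synthetic probes.

Stain-space augmentation multiplies the H and E concentration maps by
factors drawn uniformly from [0.7, 1.3] and reconstructs with the image's
own profile.

### Feature representation

Each patch is expanded into its 8 dihedral variations (4 rotations ×
optional horizontal flip), passed through a backbone feature extractor,
globally average-pooled at each tap point, concatenated, and fused per
dimension with p-norm pooling `((1/N) Σ f_i^p)^(1/p)`, p = 3. Features are
taken post-activation, so they are nonnegative as the pooling requires.
The per-dimension values are sorted before accumulation, which makes the
pooled vector bit-identical — not merely numerically close — under any
dihedral transform of the input.

The three named backbone layouts describe the ImageNet architectures the
representation is designed around: all 13 VGG-16 convolution outputs
(4224 channels), the ResNet-50 stem plus 16 post-addition block outputs
(15168), and the 11 Inception-v3 module concatenations (10048). Extractors
are pluggable callables; the package does not ship pretrained weights.
The built-in `FixtureExtractor` — a seeded random three-stage convolution
stack (1×1 mixing, two 3×3 stages, ReLU, 2× mean pooling, inputs resized
to 32×32) — has no trained semantics but responds to exactly the color and
local texture statistics the downstream models consume, and makes every
code path runnable and deterministic offline.

### Refinement

mRMR selection with the mutual-information-quotient score: the first
feature maximizes relevance I(f; y); later picks maximize relevance over
mean mutual information with the already-selected set, ties broken toward
the lower index. Mutual information is estimated by discretization:
continuous columns get 3 bins cut at mean ± sd; columns with ≤ 40 distinct
values (the cellularity grid, labels) keep their native bins. PCA (via
scikit-learn, with the largest-magnitude loading of each component forced
positive for reproducibility) optionally follows.

Named presets reproduce the study protocol: Huber/RankNet GBDTs use mRMR
alone (400/800/1000 features for VGG/ResNet/Inception); SVR uses
4000/8000/4000 features then 150 components; ranking SVM uses 50 features
then 20 components; the tissue gate skips mRMR and keeps 40 components.
The protocol is intentionally heterogeneous and the presets do not unify
it. On small tables all sizes are capped at what the table supports.

### Gate and estimators

A LightGBM binary classifier (300 trees, depth 7, feature fraction 0.6,
bagging fraction 0.8, learning rate 0.01) separates cancerous
(cellularity > 0) from benign patches; gate-negative patches receive
cellularity exactly 0 and only gate-positive patches reach a regressor,
which is trained on the cancerous subset only. The decision threshold is
0.5 on predicted probability.

Four estimators are provided:

* **Huber GBDT** (LightGBM): δ = 1, 1500 trees, depth 4, L1 = 0.001,
  feature fraction 0.6, bagging fraction 0.7, rate 0.01.
* **RankNet GBDT** (XGBoost, custom objective): pair probability
  σ(k·(F_i − F_j)) with k = 1 and binary cross-entropy summed over all
  sample pairs in *adjacent* cellularity levels; gradients and Hessians of
  that loss are supplied directly, with a 1e-9 Hessian floor. 1000 trees,
  depth 3, rate 0.01 at full scale.
* **SVR** (scikit-learn/LIBSVM): RBF kernel, C = 200, γ = 1e-4, ε = 0.
* **Ranking SVM**: linear max-margin ranker on adjacent-pair difference
  vectors, C = 1e8, both orientations included so no intercept is needed.
  The implementation uses squared slack variables (squared hinge, primal
  Newton solver): the strictly convex primal solves in a handful of
  iterations at this effectively hard-margin C, where the linear-slack
  dual solver fails to converge. Pairs are capped at 4000 by a seeded
  subsample.

Cellularities are translated to integer ranking levels 0–36 (1% bins up
to 10%, 5% bins to 90%, 1% bins to 100%; inputs snap to the nearest bin,
ties toward the lower bin). Internally a higher ranking score always means
higher cellularity; training and inference share this one convention.
Ranking scores are mapped to cellularity by KNN calibration: the mean
label of the k = 30 training samples with nearest scores (ties by index).
All estimators finish with a linear correction fitted at training time —
the affine map that gives the training predictions the mean and sd of the
training labels — followed by clipping to [0, 1]. The correction is stored
as fixed slope/intercept so single-patch predictions do not depend on
batch composition, and it is applied to gate-positive predictions only.

### Agreement metrics

ICC(A,1) from the two-way ANOVA mean squares (rows = samples, columns =
the two measurements, k = 2); Kendall's tau-b with exact pair
classification, `(n_c − n_d) / sqrt((n_p − T_x − T_xy)(n_p − T_y − T_xy))`
with n_p = n(n−1)/2; and the prediction probability
`P_K = (n_c + T_x/2) / (n_c + n_d + T_x)`, which drops pairs tied in the
reference and half-credits ties in the estimate (and is therefore not
symmetric in its arguments). No normal approximations are used.
Confidence intervals are nonparametric percentile bootstrap over samples,
2000 replicates by default; degenerate resamples are skipped and more than
50% of them abort the interval.

## Synthetic data

The patch generator renders concentration maps in OD space with the
reference stain: an eosin stroma background (mean concentration 0.45,
multiplicative per-patch jitter in [0.85, 1.15], mild pixel noise),
hematoxylin-dense malignant nuclei as overlapping rotated ellipses (radii
3–8 px on a 96 px patch) whose union area fraction is driven to within
±2% of the target cellularity (placement stops well inside the band so
achieved fractions track 1% bins; an unreachable target raises an error),
and small (2–3 px) round lymphocyte distractors present at all
cellularities — so the gate cannot succeed by detecting "any hematoxylin
at all", only by the size/texture statistics that distinguish nucleus
populations. Dataset generation assigns patients round-robin across
patches so grouped 9-fold cross-validation is feasible and every patient
spans many levels.

The feature-table generator draws a latent level uniformly from the grid
and emits `n_signal = 5` columns `scale_j · link(cellularity) + N(0, σ)`
(scale 2 + 0.75j, monotone link `sqrt` by default, σ = 0.15) plus pure
N(0, 1) noise columns (50 columns, 600 rows by default). Two properties
motivated these defaults, fixed once: the shared latent dominates the
noise eigenvalue spectrum, so PCA-based presets keep the signal; and σ is
on the order of the adjacent-level signal step at mid-grid, so adjacent
levels remain partially orderable — the regime pairwise ranking losses
are built for. These generators emulate the *statistical* structure the
pipeline feeds on, not histology: no nuclear chromatin texture, no tissue
architecture, no scanner artifacts. Passing the synthetic suites shows the
machinery is implemented correctly and can recover a planted monotone
signal at desk scale; it says nothing about accuracy on real slides.

## Desk-scale experiment profile

The printed GBDT schedules are calibrated for training sets of a few
thousand patches. The synthetic experiments run two orders of magnitude
smaller, and two capacity knobs are adjusted for that regime (everything
else — tree counts, depths, fractions, rates, C, γ, δ, k — keeps the
full-scale defaults):

* tree leaves may hold as few as 5 samples (fold training sets have only
  a handful of benign patches, below the default leaf minimum of 20);
* the RankNet learning rate is 0.2 with the round count unchanged. The
  RankNet objective converges slowly from cold scores: adjacent-pair
  gradients of middle-rank samples nearly cancel, so order diffuses inward
  from the extreme levels, and at a few hundred samples the full-scale
  rate stops far short of convergence.

The standing experiments, runnable on one CPU in a few minutes: the
monotone-recovery experiment (`cellquant.synth.monotone_recovery_tau`,
n = 600 table, 30% held out, each estimator behind its own preset) and
the end-to-end cross-validation (37 bins × 12 patches, fixture extractor,
9 patient-grouped folds, Huber estimator). Both are asserted in the test
suite; the numbers the current code produces appear in the README's worked
example.

## Known limitations

* Real pretrained backbones are an interface, not an implementation; the
  fixture extractor's features carry no learned semantics.
* mRMR cost grows as n_feat × n_features MI evaluations; the full-scale
  8000-of-15168 selection is minutes of work, not seconds.
* KNN calibration produces plateaus at the extremes of the score range
  (all k neighbors identical), which ties extreme predictions and costs a
  few thousandths of tau-b even for a perfect ranker; clipping to [0, 1]
  does the same at the boundaries.
* The bootstrap interval method is a package choice; reported interval
  widths are not comparable to analytic ones.
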