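# Methods

This note documents the model, its assumptions, the parameter choices that
matter, and what the synthetic benchmark does and does not demonstrate.

## Model

### Landmark detector

The detector is a decoder-only fully convolutional network. Heatmap
regression was chosen over direct coordinate regression because it
preserves the spatial structure of the input, tolerates frames with
missing landmarks (ablated annotations simply get zero ground-truth maps),
and needs no face-detection or cropping front end.

Scale handling is explicit: each image is expanded into a three-level
Gaussian pyramid (blur σ=1, then 2× decimation; levels at relative scales
1, 1/2, 1/4), and all levels pass through the *same* four S1 convolutional
blocks. Sharing the S1 weights across scales means the parameter count is
independent of the number of scales and pushes those blocks toward
scale-invariant features. The three S1 feature maps are bilinearly resized
to the finest level's size, averaged element-wise, and passed to S2, whose
wider kernels extract higher-order features and whose linear 1×1 head emits
one map per landmark.

The exact channel/kernel layout is configurable. The default is
S1: conv5×5(16) → conv5×5(32)+pool → conv3×3(64) → conv3×3(64)+pool
(stride 4; 240×360 input → 60×90 heatmaps) and
S2: conv9×9(128) → conv9×9(128) → conv1×1(17), all ReLU except the head.
These widths are a judgment call — the architecture contract is the four
shared S1 blocks, the multiscale average, the FCN property (no dense
layers anywhere) and the 17-channel linear head. Averaging is applied to
post-ReLU S1 outputs; resampling of the coarser levels is bilinear.

Ground-truth maps place a 3×3 binomial kernel (outer([1,2,1],[1,2,1])/4,
center normalized to 1) at the rounded scaled coordinate; at borders the
kernel is cropped with the center kept at 1. The binomial kernel is chosen
over a sampled Gaussian because it is exact, sums to 4, and keeps the
foreground pixel at exactly 1, which the Adaptive Wing loss assumes.

Pixel-center convention throughout: coordinates are 0-based (u, v) =
(column, row); image pixel u corresponds to heatmap coordinate
(u − (stride−1)/2)/stride.

### Conditional priors

For a directed pair (i, j), every training annotation contributes the
position of landmark i after the translation that would move landmark j to
the frame center. The resulting cloud (in prior-grid units, twice the
heatmap resolution) is fit with full-covariance Gaussian mixtures for each
candidate order; order selection takes the integer mean of the
AIC-minimizing and BIC-minimizing orders (ties toward the smaller order),
then the mixture at that order is kept and rasterized at cell centers.
Candidate orders default to 1–12. On the schematic synthetic faces the
selected orders are small (the pose distribution is unimodal); richer
populations with pose clusters select higher orders.

Rasterized densities are floored at ε_raster = 1e-9 so the filter's
logarithms never see zero. The floor is deliberately far below any real
density value: a larger floor (e.g. 1e-6) would contribute ~2% spurious
mass on a 120×180 grid and distort the mass bookkeeping.

The continuous fit is done before rasterization (fit-then-rasterize rather
than histogramming), and densities are not renormalized after truncation
to the grid; the mass check (grid sum × cell area ≈ mixture mass, within
2%) is part of the test suite.

### Spatial model

Each landmark i is validated against its neighborhood
N_u(i) = N_i(r) ∪ N_g: the landmarks within radius r of i on the mean
shape (distances normalized by interpupillary distance; default r = 0.25)
plus the fixed central set N_g = {LPc, RPc, NT, LMe, RMe}. Graphs are
star-shaped: only (i, j) edges, no neighbor–neighbor cliques, so the
filter's cost is linear in the edge count.

The filter computes, per landmark,

    p̂_i = exp( ln SP(p_i + ε) + Σ_j ln[ SP(p_{i|j}) ⊛ SP(p_j) + b_{j→i} + ε ] )

with SP the Softplus (1/β)ln(1+e^{βx}). Implementation semantics that the
equation leaves open, fixed here and enforced by a brute-force oracle:

- The prior grid is mean-pooled 2× down to heatmap resolution immediately
  before use; the convolution is anchored so the kernel's center cell
  (H//2, W//2) sits on the candidate position, matching the
  translate-to-center convention of the prior learning. Even-sized grids
  have no exact center cell; the induced half-cell bias is far below the
  mixture bandwidths.
- The correlation runs over *every* map cell; prior values outside the
  stored grid equal the kernel's own floor (its minimum value). Using the
  per-kernel floor rather than a global constant makes an exactly-uniform
  prior produce an exactly-constant message, so uniform priors provably
  never move an argmax.
- All edges are convolved in one batched FFT call grouped by edge;
  correctness is defined solely by agreement with the nested-loop oracle
  (max relative error < 1e-6 on random instances).
- b_{j→i} is a per-edge learnable scalar (init 1e-3) passed through
  Softplus before use, so the log argument is strictly positive for any
  non-negative input; ε = 1e-6.
- Softplus sharpness β_sp defaults to **10**. With β_sp = 1 the Softplus
  lifts near-zero prior densities to ln 2 ≈ 0.69, which flattens the
  neighbor messages so severely that the filtered blob's half-max support
  expands to the whole grid instead of shrinking; a sharper rectifier
  behaves like the identity on positive densities and restores the
  product-of-probabilities semantics the filter approximates. The bundled
  stain experiment reports the half-max support of the corrupted and
  filtered maps: at β_sp = 10 the filtered support is no larger than the
  unfiltered one, while at β_sp = 1 it expands to essentially the whole
  grid. The normalization constant of the underlying
  potential formulation is deliberately dropped; p̂ is a score, not a
  probability.

### Loss

Per landmark, Loss = (1−β)·AWing(hm, hm_ld) + β·‖x − x_sm‖², averaged over
visible landmarks; β = 0.1. AWing parameters are α = 2.1, ω = 14,
ε_AW = 1, θ = 0.5; the linear-branch coefficients

    A = ω (α−y) (θ/ε)^(α−y−1) / ( ε (1 + (θ/ε)^(α−y)) )
    C = θA − ω ln(1 + (θ/ε)^(α−y))

make the loss continuous with a continuous first derivative at |y−ŷ| = θ
(verified symbolically and numerically in the tests).

The coordinate term is computed in heatmap-pixel units (this matters for
the balance implied by β = 0.1 and is therefore stated explicitly). During
training the spatial model's coordinate x_sm comes from a soft-argmax over
ln p̂ with temperature 0.1 — hard argmax has zero gradient, so a
differentiable surrogate is unavoidable; inference uses hard argmax.
Invisible landmarks (including those pushed out of frame by augmentation)
are masked out of both terms.

Joint runs use a coordinate warm-up (default 5 epochs): while the detector
output is still flat, the soft-argmax of the spatial field is essentially
the field centroid, and the coordinate residual (~hundreds of squared
cells) dwarfs the heatmap term (~0.02) — its gradients then deform the
maps into tilted planes before blobs can form. For the warm-up epochs the
coordinate term is excluded from the gradient (the reported loss is always
the full objective); once blobs exist the filtered soft-argmax sits within
a few hundredths of a cell of the truth on well-formed maps, so the
coordinate gradient refines rather than fights the heatmap term. The
objective itself is unchanged; this is purely an optimization schedule.

### Training protocol

Adam (β1 = 0.9, β2 = 0.999), batch 16, base learning rate 1e-4 reduced to
1e-5 at epoch 25 and 1e-6 at epoch 40, at most 120 epochs, early stopping
after 10 epochs without training-loss improvement (tolerance 1e-6).
Augmentation per image: affine with scale ~ U[1.05, 1.5], per-axis
translation magnitude ~ U[0, 10%] of the frame (random sign), rotation
~ U[−20°, 20°], horizontal flip with probability 0.5 (flip permutes
landmark identities by the schema's mirror map). Pixels are warped
bilinearly; landmark coordinates are always transformed analytically, never
resampled. Detector-only and joint modes are both supported; joint mode
trains the per-edge biases together with the CNN weights and initializes
fresh by default. Validation splits are off by default (stopping is on the
training loss).

## Landmark schema

The 17 identifiers are the five "well-defined" points — left/right pupil
centers, nose tip, left/right mouth extremities — plus three points per
eyebrow (ends and mid) and three per eye (both corners and an upper-lid
mid point). When only 68-point annotations exist, the five extra points
are derived rather than manually labeled: pupil centers as centroids of the
six eye-contour points (iBUG 37–42 / 43–48, 1-based), nose tip as iBUG 31,
mouth extremities as iBUG 49 and 55. This derivation is an approximation
of manual enhancement — derived pupil centers are eye-opening centroids,
which sit slightly above a true pupil on downcast gazes. The index table
ships as data and is configurable.

## Synthetic data

The generator emulates the geometry of annotated face datasets, not their
appearance: a posed (rotation ±15°, scale 0.85–1.15, translation ±5%),
per-landmark-jittered (σ = 0.02 unit-face) canonical 17-landmark shape,
rendered as a schematic grayscale face (head ellipse, brow/eye strokes,
dark pupils with a bright glint, nose and mouth strokes) whose stroke
geometry follows the landmarks exactly. Pose parameters are uniform; the
canonical interpupillary distance is 0.40 of the face width.

What passing on this population shows: the pipeline's mechanics are correct
— the CNN can learn localized appearance, the priors capture the pairwise
geometry, the filter suppresses spatially inconsistent maxima, the joint
loss trains end to end. What it does not show: robustness to texture,
illumination, occlusion, identity variation or extreme pose — the renderer
has none of these. Accuracy numbers on synthetic faces are therefore not
comparable to benchmarks on photographic datasets.

## Scaled-down study sizes

The bundled experiments run on one CPU in minutes, with sizes chosen as
the smallest that exercise every mechanism: 500 training / 100 held-out
64×96 faces, a narrow detector (S1: 8-8-16-16 channels, one pooling stage;
S2: conv5×5(32) → 1×1(17)), 10 epochs at a constant 2e-3 learning rate
(the 120-epoch schedule above is pointless at this length). The small
configuration uses heatmap stride 2 rather than the default 4: at 64×96
the 10%-interpupillary PCK threshold is 2.4–3.5 px, smaller than a
stride-4 cell's half-diagonal (2.83 px), so hard-argmax quantization alone
would dominate the error budget. At the default 240×360 resolution the
stride-4 default is appropriate.

## Numerical choices and degenerate inputs

- Heatmap argmax ties break to the smallest row-major index; all-zero maps
  mark the landmark not-visible.
- `.pts` files are 1-based; −1 on read, +1 on write.
- The stain-injection utility rescales its blob so the stained cell equals
  the map's maximum *exactly*, and truncates the blob at 4σ so the original
  peak is untouched — the corrupted map has exactly two tied global maxima.
- GMM fits use fixed-seed k-means initialization, best of 3 restarts;
  rank-deficient sample clouds get extra covariance regularization and a
  warning.
- Frames with zero interpupillary distance are excluded from metrics with
  a warning. The "best-90%" NME is the 90th percentile of the pooled
  per-landmark normalized errors (per-landmark pooling, matching the
  cumulative-error-distribution reading of that figure of merit; per-frame
  pooling is the other defensible choice).
- Training aborts with the offending batch's source ids if the loss goes
  non-finite.

## Known limitations

- The filter's inference-time input is clipped at zero (its contract
  assumes non-negative unary maps); during training raw linear-head
  outputs pass through Softplus unclipped.
- Bilinear resampling of the coarser S1 levels makes translation
  equivariance only approximate near borders and for odd shifts.
- The autodiff engine implements exactly the operator set used here; it is
  not a general-purpose framework (no GPU, no higher-order gradients).
- Prior banks, checkpoints and heatmap stacks are tied together by a
  schema hash; mixing artifacts from different schemas is refused rather
  than silently reindexed.
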