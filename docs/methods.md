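# Methods

## Problem and pipeline

The cardiothoracic ratio (CTR) is read off a chest radiograph as
TCD/TTD — the widest horizontal extent of the cardiac silhouette over the
widest internal width of the chest. The package automates the reading in
three stages: preprocessing, heart/lung segmentation with a small U-Net,
and a deterministic geometric measurement on the cleaned masks, with a
projection-specific cardiomegaly classification (CTR > 0.55 standing/PA,
CTR > 0.58 supine/AP, both strict).

## Preprocessing conventions

* **Rescale** — stored pixel values are mapped through the DICOM modality
  transform `v·RescaleSlope + RescaleIntercept`. For projection
  radiography there is no true Hounsfield scale; the rescale transform is
  the only physically defensible normalization of stored values, and any
  remaining affine offset is removed by standardization.
* **Polarity** — MONOCHROME1 images are inverted as `v' = max(v) − v`
  using the per-image maximum rather than `2^BitsStored − 1 − v`. This is
  robust to wrong bit-depth metadata; the affine difference between the
  two conventions is again absorbed by standardization. The operation is
  idempotent and, when the image minimum is 0, an involution.
* **Resize** — direct anisotropic resize to the model grid (default
  256×256), bilinear for images and nearest-neighbour for masks. No
  letterboxing: CTR is a ratio of horizontal widths and is invariant under
  axis-aligned scaling. The original shape is retained on the image object
  for back-mapping.
* **Standardization** — a single scalar mean/std pooled over all pixels of
  the *training* subset only ("dataset-level" statistics); constant pooled
  input is rejected as degenerate.
* **Split** — seeded shuffle with `|train| = floor(0.8·n)`, which maps
  1059 annotated images to exactly 847 training and 212 validation images.
* **Augmentation** (training only, geometric only) — independent
  horizontal/vertical flips (p = 0.5 each; flip rates are a package
  default, vertical flips included deliberately), rotation about the image
  center drawn from ±0.2 rad, and per-axis shifts drawn from ±20% of each
  dimension. One sampled transform is applied to the image (bilinear) and
  both mask channels (nearest), with out-of-canvas regions filled with 0 —
  background-neutral after standardization. A null configuration is a
  bit-exact identity.

## Segmentation model

The task is multi-**label**: the cardiac silhouette overlies the lung
fields, and the annotation convention overlaps the two masks there, so the
output head is a per-channel sigmoid (heart, lungs) rather than a softmax.
The reference architecture has five resolution levels with base width 16
doubling per level, two 3×3 convolution + ReLU layers per block, 2×2 max
pooling, a symmetric decoder with 2×2 stride-2 transposed convolutions and
skip concatenation, no batch normalization, and a two-channel 1×1 sigmoid
head — 1,940,834 trainable parameters (1.94 M).

No deep-learning framework is used: convolutions (im2col + BLAS matmul),
transposed convolutions, pooling, the analytic loss gradients, reverse-mode
backpropagation and Adam are implemented in NumPy (`autoctr._nn`). The
gradients are verified against central finite differences in the test
suite.

**Loss.** `L = w_f · focal + w_d · dice` with equal unit weights by
default. Focal loss is the mean over pixels of `−α_t (1−p_t)^γ log p_t`
with α = 0.25, γ = 2 (standard values; configurable), probabilities
clipped to [1e−7, 1−1e−7]; with γ = 0, α = 0.5 it reduces to half the
binary cross-entropy. Dice loss is `1 − (2Σpt + s)/(Σp + Σt + s)` with
smoothing s = 1, computed per (sample, channel) and averaged.

**Optimization.** Adam at learning rate 0.001 for 56 epochs at batch size
64 in the reference schedule, with reduce-on-plateau scheduling
(factor 0.5, patience 5 epochs, floor 1e−6 — common defaults,
configurable); the learning-rate trace is non-increasing. Training is
seed-pinned and reproducible; a non-finite loss raises a
training-diverged error rather than continuing silently.

## Geometric measurement

Probability maps are thresholded strictly at 0.5. The heart channel keeps
only its largest 4-connected component with holes filled; the lung channel
keeps every component with area ≥ 25% of the largest (separate lung fields
or one mediastinum-merged component) with per-component hole filling —
this is what rejects line artifacts such as drains and cables.

Widths use the inclusive pixel convention `max_col − min_col + 1` for both
TCD and TTD, so the ratio treats both symmetrically; consequently
`a + b + 1 = tcd` when the heart spans the midline. The midline — needed
only for the a/b decomposition, since TCD is provably independent of any
midline inside the cardiac span — is the median over occupied rows of the
midpoint of the lung extent in that row (spinous processes are not
segmented), rounded to nearest-even. TTD is measured on the lung channel,
whose annotation convention covers the inner thoracic width including the
mediastinal shadow.

## Phantoms: what they emulate, and what they do not

Each phantom has two elliptical lung fields (dark), an optionally rotated
elliptical heart (bright) overlapping the lung region, a soft-tissue
thorax, Gaussian noise (σ ∈ [0.01, 0.03] of full scale), and 0–3 bright
line segments 1–3 px wide emulating drains/cables. The lungs channel
includes the inter-lung mediastinal band, matching the annotation rule
above, and the heart and lung masks always overlap. Intensity ordering is
radiographic Monochrome2: lung < soft tissue < heart.

Geometry is drawn per phantom: thoracic width 70–90% of the canvas,
analytic CTR uniform on 0.40–0.70 (both sides of the thresholds), heart
aspect ratio 0.55–0.80, rotation ±0.1 rad, heart center 5–15% below the
canvas midline. The rotated-ellipse width `2√(a²cos²θ + b²sin²θ)` gives a
closed-form TCD, and the outer lung span a closed-form TTD, so measured
CTR can be checked against an exact value; rasterization contributes
O(1 px) per width, bounded by 0.02 in CTR for TTD ≥ 100 px.

Phantoms deliberately do **not** model ribcages, scoliosis, asymmetric
projections, pathology, exposure variation, or pediatric morphology.
Passing phantom tests demonstrates that the architecture can learn
overlapping two-channel segmentation and that the geometry stage is exact;
it does not certify clinical performance on real radiographs.

## Evaluation and statistics

IoU and F1 are micro-averaged over the pooled pixels of a subset
(macro-per-image averaging would be the alternative; the micro choice is
documented and isolated in one place), reported per channel and as the
equal-weight mean of the heart and lung channels. The identity
`F1 = 2·IoU/(1 + IoU)` is property-tested.

Measurement tables (per image and observer: TCD, TTD, CTR, time) are
compared nonparametrically: two-sided Mann-Whitney U between the model and
the mean of the human observers (after Tukey-fence outlier removal,
k = 1.5, closed fences — the standard operationalization of "extremes and
outliers"), Kruskal-Wallis across human observers, and Spearman rank
correlation on paired per-image values, reported as ρ and ρ² with the
p-value. Normality is screened with Lilliefors and Kolmogorov-Smirnov
tests. Wall-clock per-image timing is recorded in the measurement CSV as
informational output only; it is hardware-dependent and asserted nowhere.

## Problem sizes in the test suite

The shared training check runs a three-level, base-8 U-Net on 64 training
phantoms (plus 16 validation phantoms) at 128×128 for 15 epochs at batch
size 8 without augmentation, fully seed-pinned; it reaches pooled
validation IoU well above the asserted 0.80 (≈0.97 at the pinned seed).
Geometry and metric properties are checked over 100 random phantom
geometries and 1000 random mask pairs respectively; statistical analogues
use n = 100 images × 4 observers and 500 null replicates.

## Known limitations

* The NumPy network trains on CPU only and is sized accordingly; the
  reference 5-level/256×256 configuration is instantiable and used for
  parameter accounting and shape contracts, while training-based checks
  use the scaled-down configuration above.
* Midline estimation assumes roughly symmetric lung masks; gross scoliosis
  or single-lung masks shift the a/b decomposition (not the CTR itself).
* Projection must be supplied (DICOM ViewPosition, sidecar, or CLI flag);
  without it classification is INDETERMINATE by design.
* The mask store keeps full-resolution uint8 channels; for very large
  datasets a chunk/compression policy would be worth revisiting.
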