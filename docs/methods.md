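# Methods

## The screening problem

Mild diabetic eye disease is hard to classify directly from raw fundus
photographs: the lesions that distinguish a mild case from a healthy retina
(microaneurysms, soft exudates, early optic-nerve change) cover a tiny
fraction of the pixels, and fundus images additionally vary in illumination
and contrast. The package therefore follows a two-stage design: classical
image processing first makes the anatomy explicit (enhanced green channel,
vessel mask, exudate candidates), and a compact CNN then classifies the
explicit representation. The central empirical claim the code supports is
directional: *the preprocessed representation classifies at least as well
as the raw image under the same training budget*.

## Enhancement operators

All operators take and return integer gray images, round half up, and are
deterministic.

* **Green channel.** Vessels absorb most in the green band, so the green
  channel carries the best vessel/background contrast; red is near
  saturation and blue is noisy.
* **CLAHE.** Tile-wise histogram equalization with a clip limit
  `n_CL = n_CLIP · (n_x n_y / n_gray)`. Clipped mass is redistributed
  uniformly over all bins in one pass; per-pixel output blends the four
  surrounding tile mappings bilinearly (anchored at tile centers, clamped
  at the border band). Defaults: 16×16 px tiles, 256 levels, clip factor
  2.0 — a mild setting; the clip factor bounds the local contrast gain at
  roughly ×2, which is enough to lift faint vessels without turning sensor
  noise into structure.
* **Illumination correction.** `p' = p + μ_D − μ_L` with `μ_L` a box mean
  (default 31 px, edge-replicated borders) and `μ_D` defaulting to the
  image's own global mean. This removes slowly varying shading; with the
  self-targeted default the global mean is preserved to within rounding.
* **Contrast stretch.** The affine map sending the observed minimum to 0
  and maximum to `Γ−1`. A constant image raises a degenerate-input error
  rather than dividing by zero; callers skip the stage. (The symbolic form
  of this map is sometimes printed with its endpoints swapped, which would
  invert the image; the implementation is the standard orientation-
  preserving min-max stretch, since the stage's purpose is enhancement.)
* **Median filter.** Odd-window sliding median with edge replication;
  removes impulse noise while preserving edges, and commutes with monotone
  relabelings away from the border.

## Morphology

Erosion/dilation/opening/closing on boolean masks with the standard set
semantics. Cells outside the image are background: they can never satisfy
an erosion probe and never contribute to a dilation. Under that convention
the erosion–dilation duality `A ⊕ B = ¬(¬A ⊖ B̂)` is exact away from the
canvas border, and opening/closing are idempotent, anti-extensive /
extensive. The default structuring element is the full 3×3 square (no stage
of the source pipeline specifies a shape).

## Threshold selection

* **ISODATA (intermeans).** A threshold `t` is a fixed point of
  `t ← (mean below t + mean above t)/2`. On vessel imagery the histogram
  has a small dark vessel mode and a broad background mode; the broad mode
  can host a *second* fixed point, and plain iteration from the global mean
  sometimes stalls there. The implementation therefore scans all integer
  thresholds for fixed points (cumulative-sum arithmetic, O(L)), returns the
  smallest — the dark/background boundary, which is the one vessel
  extraction needs — and refines it by iteration to the requested
  tolerance.
* **Otsu.** Full class-statistics bookkeeping: weights `w₁, w₂`, means
  `m₁, m₂`, variances, within-class and between-class variance and the
  identity `σ_w²(t) + σ_B²(t) = σ²`. The returned threshold maximizes
  `σ_B²` (equivalently minimizes `σ_w²`); ties — which genuinely occur on
  histograms with empty gaps between modes, where `σ_B²` is flat across the
  gap — resolve to the smallest threshold.

## Segmentation pipelines

* **Vessels.** Green → CLAHE → illumination flattening → ISODATA, darker
  class → 3×3 closing → removal of 8-connected components below 30 px.
  Vessels cover a few percent of a fundus image; if the dark class claims
  more than 20% of the pixels the threshold is splitting background
  texture and the empty mask is returned instead.
* **Optic disc.** Green → CLAHE (plus a min-max stretch when the enhanced
  image still spans less than 200 gray levels) → 3×3 median → Sobel edge
  map thresholded at its 95th percentile → circular Hough transform with a
  1 px accumulator in center and radius, radius range `[side/20, side/6]`.
  Raw vote maxima favor large radii (a big circle passes near more clutter
  edges), while perimeter-normalized votes favor tiny bright lesions; the
  detector therefore takes the top-8 raw-vote candidates, keeps those with
  at least 30% perimeter support, and picks the one with the highest
  area-weighted interior-minus-annulus brightness — the optic disc is, by
  anatomy, the large bright circle. The returned mask is the filled circle
  refined by Otsu thresholding in a box 1.5× the radius (keeping bright
  pixels, closing over vessel shadows, falling back to the full circle if
  refinement removes more than half of it). A flat or circle-free image
  raises a detection-failure error. The 95th-percentile edge threshold
  (rather than the 90th) was chosen because the denser edge map lets
  vessel clutter out-vote the disc rim on a few percent of images; the
  choice was validated on 600 generated images (0 failures).
* **Exudates.** Green → disc removal (background-mean fill) → vessel
  inpainting (iterative 7×7 neighborhood-mean) → illumination correction →
  median filter → Otsu, bright class → 3×3 opening → disc exclusion.
  Two orderings matter and are deliberate: removal happens *before*
  illumination flattening (dark vessels otherwise drag the local mean down
  and leave bright halos), and CLAHE is *not* applied on this path — local
  contrast amplification widens the background mode until Otsu's
  between-class criterion prefers splitting background texture over
  isolating the lesion class. Exudates are rare outliers; if the bright
  class exceeds 5% of the image the threshold is judged non-lesional and
  the empty mask is returned.

## Architectures and the numpy engine

The screening CNN is declarative: five same-padding 5×5 convolutions with
filter banks 64·k, 128·k, 256·k, 512·k, 512·k (k=1 reference), each
followed by 2×2/stride-2 max pooling and ReLU (pooling before ReLU — the
two commute for max pooling, so this ordering is also numerically safe),
then flatten, dropout 0.5, a 64-unit ReLU dense layer and a single-unit
sigmoid head for binary screening (softmax for >2 classes). At 224 px input
the spatial chain is 224→112→56→28→14→7 and the flatten width 25,088. The
reference input side is 224 (a 244 px input would not produce that chain).

VGG16, Xception and DenseNet-121 are encoded as parameter-bearing layer
lists (convolutions, separable convolutions as depthwise+pointwise without
bias, batch normalization counted as 4 parameters per channel including the
moving statistics, dense heads). Their totals — 138,357,544 / 22,910,480 /
8,062,504 with the 1000-class ImageNet heads — are reproduced exactly from
topology; no pre-trained weights are loaded (weight files are a
network-dependent optional extra). Transfer customization replaces the
ImageNet head with a pooled 64-unit classifier and freezes the base
entirely (feature extraction) or all but the trailing *n* parameter-bearing
layers (fine-tuning).

Training runs in `dedscreen.nn`, a float32 numpy engine (sliding-window
im2col convolutions, reverse-mode gradients, RMSprop and Adam, inverted
dropout, binary cross-entropy on logits). It is single-threaded and fully
seeded: identical seeds give identical histories.

## Evaluation protocol

Stratified 80/20 split (per-class train share `round(0.8·n)`, clamped so
both sides are non-empty), stratified 10-fold assignment, balanced
undersampling to `n` per class, and confusion-matrix metrics where any
ratio with a zero denominator is reported as `None`, never silently 0.
Training defaults follow the study protocol: 224 px input, RMSprop for the
screening CNN (Adam for transfer models), batch 32, learning rate 3e-4,
binary cross-entropy, 50 epochs, 10-fold CV.

The scaled-down end-to-end experiment (`run_end_to_end`) uses 100 images
per class, a 64 px / 8-filter variant of the screening CNN, 10 epochs, and
mini-batch 8. The batch size is scaled down with the dataset just as the
width and epoch count are: 160 training images at batch 32 would give the
optimizer only 50 update steps, too few to converge reliably, whereas batch
8 gives 200. The preprocessed arm feeds three channels: enhanced green,
vessel mask, exudate-candidate mask.

## What the synthetic generator does and does not show

The generator emulates the *structure* of screening data: an orange-red
background, a bright circular optic disc with a pale cup (enlarged in the
glaucoma class), a branching dark vessel tree emerging from the disc rim,
class-specific lesions (bright Gaussian exudate blobs placed away from disc
and vessels for DME; 1–3 px dark dots near vessels for DR), a linear
illumination ramp, and Gaussian sensor noise, all at 128 px. Lesion sizes
and contrasts for "mild" disease are free choices — no public dataset was
used to calibrate them.

It does **not** model photographic realism: no camera optics, no 45°
field-of-view mask, no texture, no haemorrhages, no inter-patient anatomy
variation, and lesion contrast is higher than clinical mild disease.
Passing tests therefore demonstrate that the pipeline's mechanisms are
implemented correctly and interact as designed — not that the measured
accuracies transfer to Messidor-class clinical data, where the source
study's own numbers (80–100% accuracy depending on class and
preprocessing) were obtained.

## Numerical conventions

0-based `(row, col)` coordinates, top-left origin. Intensities round half
up after every enhancement stage. CHT accumulator resolution is 1 px in
all three dimensions with ties broken by votes desc, then smallest radius,
then row-major center order. Seeded `numpy` Generators drive all
randomness; dataset generation spawns one child seed per image below 2³¹.

## Known limitations

* The brightness-scored disc detector assumes one dominant bright circular
  structure; images with several (e.g. large confluent exudates at disc
  scale) could mislead it.
* The plausibility gates (20% vessels, 5% exudates) trade recall on
  extremely diseased images for specificity on healthy ones — appropriate
  for screening, but a different operating point than lesion grading.
* The numpy engine supports the linear screening topology only; the
  transfer architectures are buildable and countable but not trainable in
  this package (their role here is parameter accounting and customization
  semantics).
* Non-right-angle rotations and crop-resizes in augmentation interpolate
  bilinearly and so do not exactly preserve the pixel multiset.
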