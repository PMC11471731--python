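# Methods

## Scope and data model

All processing is per 2-D axial slice. The working currency is a raster
with explicit in-plane spacing in millimetres: intensity images (FLAIR),
probability maps (GM/WM/CSF, values in [0, 1]) and boolean masks (WMH,
ventricles, binarized tissue). Pixel (row, col) sits at physical
(row·spacing_y, col·spacing_x) mm; the default spacing is 0.9 × 0.9 mm.
Slice thickness is carried for provenance but never used: no 3-D
morphology or 3-D distances are offered, because every rule here is
stated and applied in the slice plane. Images combined in one run must
share geometry exactly; a missing spacing (e.g. PNG input) is an error,
never a silent default.

## Mask post-processing

Tissue probability maps are binarized at an inclusive threshold
(pixel ≥ t) and cleaned with a 3×3 opening followed by a 3×3 closing.
Defaults: GM 0.10 (deliberately permissive — the refinement step removes
the junk), WM 0.90 (only certain WM), CSF 0.50. Only the ordering of
these thresholds is principled (GM low, WM high, CSF between); the
numbers are exposed in `MorphologyConfig`.

The WMH mask is inflated once with a 5×5 square element, absorbing the
uncertain rim of lesion segmentations. The ventricle mask is closed with
a 9×9 element (removing dispersed punctate noise) and then dilated with
a 9×9 element three times. Each 9×9 dilation pushes the boundary at
least 4 px outward, so three passes guarantee ≥ 12 px ≈ 10.8 mm of
expansion at 0.9 mm spacing — past the 10 mm band in which tissue
segmentation is prone to mislabeling GM near the ventricles. The
guarantee is checked at run time against the actual spacing and a
warning is emitted if the configured element/iterations cannot reach
10 mm.

All morphology uses square structuring elements and one pinned border
convention: pixels outside the image are background, and opening/closing
are composed explicitly from erosion and dilation under that convention.
This makes every operator reproducible bit-exactly and lets the test
suite compare against a definitional shift-and-combine oracle with exact
equality. The cost is that closing is not extensive within one element
radius of the image border; anatomy in practice (and in the phantoms)
never touches the border.

## Specialized GM mask

The union of the four post-processed non-GM masks (WM, CSF, inflated
WMH, inflated ventricles) is removed from the binarized GM mask, and the
difference is cleaned with the same 3×3 opening + closing. Before
cleanup the result is exactly `gm AND NOT union` — disjoint from the
union and contained in the GM mask, which the tests assert as
invariants. The result is not an anatomically faithful cortex
segmentation and is not meant to be one: it is a reference contour such
that "within 5 mm of GM" reliably means "near the cortex, not near
periventricular debris".

The orientation of the subtraction matters and is sometimes stated the
other way around: subtracting GM *from* the union would yield non-GM
tissue, useless as a cortex reference. GM minus union is implemented.

## Lesion geometry

Lesions are 8-connected components of the WMH mask, enumerated in
raster-scan order of their first pixel. A contour is the set of mask
pixels with at least one background 4-neighbour (image-edge pixels
included), taken at pixel centers in mm; no sub-pixel interpolation is
attempted, so all distances are center-to-center. Contour-to-contour and
centroid-to-contour minima are computed with a KD-tree over the
reference contour — exact, and verified against O(n·m) brute force.

"Mass center of a contour" admits two readings. The default is the
centroid of the component's pixel set; the centroid of the contour
points only is available via `center_mode="contour"`. A contour-point
centroid is biased by boundary irregularity, hence the default.

Classification consumes the **original** WMH components, not the
inflated ones — the 5×5 inflation exists to build the union mask, not to
change lesion geometry (`use_inflated_wmh` restores the other reading).
Ventricle distances are measured against the denoised (closed,
pre-dilation) ventricle mask: measuring a ≤ 5 mm rule against a mask
already dilated by > 10 mm would make the rule vacuous
(`use_inflated_ventricles` restores the literal post-processed mask for
comparison).

## Classification rules

Evaluated strictly in order, with exact boundary semantics:

1. shortest contour distance to ventricles ≤ 5 mm → PE (inclusive);
2. centroid distance to ventricles ≤ 10 mm → PE (inclusive);
3. shortest contour distance to GM < 5 mm and area < 20 mm² → JC
   (both strict);
4. else → PA.

A lesion overlapping the ventricle mask has distance 0 and is PE with no
special case. An empty ventricle mask skips rules 1–2 (nothing can be
PE); an empty GM mask skips rule 3 (nothing can be JC); both warn.
Degenerate inputs (empty WMH mask) yield an empty labeled map. The
boundary tests place hand-built lesions at exactly 5.0 mm, 10.0 mm,
5.0 mm and 19/20 mm² to pin each operator.

## Evaluation metrics

Six pixel-level metrics from one-vs-rest confusion counts: accuracy,
precision, recall/sensitivity, specificity, DSC and IoU, tied by
DSC = 2·IoU/(1+IoU) (asserted to machine precision). Per-class reports
use the full image grid for true negatives (an ROI mask can restrict
this), support = truth pixels of the class, and both macro and
support-weighted averages. Zero-denominator policy: empty-vs-empty
scores 1 and is flagged `degenerate`; empty-vs-nonempty scores 0. A
class absent from the truth is reported absent rather than as a
meaningless 0/0 row.

## Phantom generator

Each phantom is a seeded caricature of one lesion-bearing slice:
elliptical head, ~3 mm CSF rim, ~4.5 mm cortical GM ribbon inside it,
WM interior, and two mirrored tilted ellipses as "butterfly" ventricles.
Probability maps are piecewise constant (dominant tissue 0.90–0.95) and
sum to ≤ 1; FLAIR intensities are piecewise constant (CSF 0.10 <
WM 0.45 < GM 0.62 < lesion 0.92) plus Gaussian noise (σ = 0.03). Head
axes, rim/ribbon thickness, ventricle pose and every lesion are drawn
from one `numpy` Generator, so a bundle is bit-reproducible from its
seed.

Lesions are ellipses (axis ratio ≤ 2, default geometric-mean radius
1.2–3.0 mm) planted by rejection sampling in class-specific candidate
regions, then re-verified by direct distance measurement before
acceptance: PE contours within 3.5 mm of the ventricles; PA lesions
≥ 6.5 mm (contour) and ≥ 11.5 mm (centroid) from the ventricles and
≥ 6.5 mm from the GM ribbon; JC lesions 2.0–3.4 mm from the ribbon with
area ≤ 18 mm². These bounds are the rule thresholds offset by a 1.5 mm
safety margin (and 2 mm² on area) — larger than half a voxel diagonal,
so pixelation can never flip a planted class; exact-boundary behaviour
is deliberately *not* tested on phantoms but on hand-built masks. The
JC floor of 2.0 mm additionally keeps the 5×5 WMH inflation (reach
1.8 mm at 0.9 mm spacing) from notching the ribbon out of the
specialized GM mask. Placement failure after bounded retries raises an
error naming the class; the anatomy is resampled up to 20 times first.

What the phantoms do not emulate: MRI physics (bias fields, partial
volume, through-plane effects), real cortical folding, realistic lesion
texture, or segmentation errors of upstream tools. Passing the recovery
tests therefore demonstrates the correctness of the rules, geometry and
mask algebra — not clinical performance on patient data.

The adversarial variant (`inject_gm_leak`) emulates the one upstream
failure mode the pipeline is designed against: a patch of high GM
probability in periventricular WM. A small PA lesion is planted with
centroid ~12 mm from the ventricles and the leak is placed between
lesion and ventricle, < 3.5 mm from the lesion but entirely inside the
10.8 mm ventricle-inflation reach. A classifier using the raw binarized
GM map calls that lesion JC; the pipeline removes the leak via the union
mask and classifies it correctly. Over adversarial batches this shows up
as pipeline JC precision ≈ 100 % vs ≈ 65–70 % for the baseline arm.

## Surrogate model

The image-to-mask surrogate follows the pix2pix construction: a
three-level encoder–decoder generator with skip connections
(4×4 stride-2 convolutions, instance normalisation, leaky-ReLU encoder /
ReLU decoder, sigmoid output) and a three-layer convolutional patch
discriminator conditioned on the FLAIR input; losses are patch-level
binary cross-entropy plus L1 × 100, optimised with Adam
(lr 2·10⁻⁴, β₁ 0.5), batch size 1, per-image min-max normalised inputs,
outputs binarized at 0.5 for metrics. It is written directly in numpy
(im2col convolutions with handwritten backprop, verified by
finite-difference tests) and sized for a desk: 16 base channels and
128-px images train in ~25 s for 50 pairs × 5 epochs on one CPU.

Training pairs come from `generate_pairs`, whose targets are produced by
running the *actual* mask pipeline on each phantom — the model learns
the pipeline, not the anatomical truth. An 80/20 train/test split is
applied in pair order; held-out evaluation phantoms use a disjoint seed
range. Epoch 0 of the training history records the untrained generator
as the negative-control baseline. Working sizes: a 64-px slice at 0.9 mm
is a 57.6 mm field of view, too small to hold the anatomy together with
the 11.5 mm paraventricular clearance, so the smoke-scale configuration
is 128 px at 0.9 mm (115 mm field); the architecture is fully
convolutional and accepts any size divisible by 8. Typical smoke-scale
results: held-out DSC 0.5–0.9 after 5 epochs vs ~0.15 untrained, and
≥ 95 % planted-class recovery when the predicted mask replaces the
pipeline's GM mask in classification. Instance normalisation is the one
deliberate stabiliser: without any normalisation the sigmoid output
saturates toward the empty mask under the 12:1 background/foreground
imbalance and the model cannot escape within a smoke-scale budget.

## Numerical choices and limitations

* Binarization is inclusive (≥ threshold); documented so results are
  bit-reproducible.
* Distances are exact center-to-center minima (KD-tree); no fast
  approximate path is enabled.
* Components: 8-connectivity for lesions (standard for bright blobs);
  contours use 4-neighbour background adjacency so diagonal necks do not
  hide boundary pixels.
* Report averages over classes with zero total support fall back to
  uniform weights.
* The CLI writes masks as 0/1 NIfTI or 0/255 PNG; probability PNGs are
  8-bit quantised (lossy), NIfTI float32 (lossless for these maps).
* Known limitations: no 3-D support, no DICOM, no bias-field or
  registration handling (upstream tools own those), and the surrogate is
  a demonstration-scale model — nothing here should be read as a claim
  about dataset-scale segmentation accuracy on clinical images.
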