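# Methods

## Scope and model context

`pestkit` implements, as a standalone library, the custom components
of an enhanced YOLOv5s-style single-stage detector for passion-fruit
pest imagery: a point-line-distance bounding-box regression loss
(PLDIoU), CBAM channel/spatial attention as applied in four parallel
neck streams, Mosaic-9/Mixup data augmentation with exact label
remapping, K-means anchor recalculation, dataset I/O and splitting,
and the AP/mAP/F1/mDT evaluation stack.  The detector backbone, neck
and head themselves, end-to-end training, and pretrained weights are
out of scope: every component here is exercised on synthetic labeled
data and checked against independent oracles instead of GPU training
runs.

## The PLDIoU loss

For a predicted box C and target box G (axis-aligned, continuous
pixel coordinates, area = width x height with no one-pixel
adjustment), let l be the line through their centers and A the
minimum enclosing box of C and G.  With d the distance from A's
center to l:

    R       = d^2
    PLDIoU  = IoU(C, G) - eta * R
    L       = 1 - IoU(C, G) + eta * R

The line through p and q is stored as coefficients alpha = q_y - p_y,
beta = q_x - p_x, lambda = q_x p_y - p_x q_y, and the squared distance
is evaluated as (alpha x - beta y + lambda)^2 / (alpha^2 + beta^2).
The sign of the beta term is the one under which the two defining
points actually lie on the line; with a plus sign the expression is
not a point-line distance at all (it does not vanish at p and q).

Geometric consequences that the test suite asserts:

* R = 0 exactly when the centers of C, G and A are collinear — in
  particular for every equal-sized pair, since A's center is then the
  midpoint of the two box centers.  For such pairs the loss reduces
  to the plain IoU loss.
* The loss is symmetric in (C, G), translation-invariant, and the raw
  penalty scales as s^2 under uniform rescaling.
* PLDIoU <= IoU always, and L >= 1 - IoU.

### Parameters

* `eta` (default 10, dimensionless): weight of the penalty relative
  to the IoU term.  With the raw penalty, eta * R is in squared
  pixels and can dominate the IoU term for well-separated boxes;
  PLDIoU below -1 is possible and no clamp is applied.
* `normalize_penalty` (default off): divides R by the squared
  diagonal of the enclosing box.  This DIoU-style variant is
  scale-invariant and bounded by 1/4 (the center of A is never
  farther than half its diagonal from any line through its interior).
  The raw form is the published one; whether eta = 10 was tuned
  against a raw or normalized penalty is not stated anywhere, so both
  are exposed and the raw form is the default.

Degenerate cases: coincident centers give a degenerate line and
R := 0 (the penalty measures center offset; zero offset means zero
penalty, and the convention avoids 0/0).  A pair with zero union area
has IoU := 0 and the loss stays finite.

### Gradient

`pldiou_loss_grad` is a hand-derived analytic gradient with respect
to the eight corner coordinates, chained through the box centers and
the enclosing-box corners.  The loss is piecewise smooth; at corner
ties and at box-contact boundaries the prediction-side subgradient
branch is returned.  Tests compare it with central finite differences
(step 1e-6) at 100 random non-degenerate pairs and require 1e-4
relative agreement, for both raw and normalized penalties.

## CBAM attention

Channel attention pools the C x H x W input over space (average and
max), passes both pooled C-vectors through a shared bottleneck MLP
(C -> C/r -> C, ReLU between, no biases), sums and applies a sigmoid;
spatial attention pools across channels, stacks [avg; max], convolves
with one 7 x 7 kernel (zero padding 3, stride 1, single bias) and
applies a sigmoid.  The refined map is F'' = Ms(F') * F' with
F' = Mc(F) * F.  Both attention maps are strictly inside (0, 1), so
the output never exceeds the input elementwise — the suite checks
this, shape preservation, and the closed forms (all-zero parameters
give Mc = Ms = 0.5 and output = input/4).

Choices where the published description is silent or inconsistent:
the reduction ratio defaults to r = 16 (the conventional CBAM value;
any divisor of C is accepted); the pooling stack order is [avg; max]
per the defining equation, although the surrounding prose describes
max-then-average — the order is configurable (`pool_order`) and the
two differ whenever the kernel is not symmetric across its two input
channels.  The "4CBAM" helper applies four independently
parameterized blocks to the four neck feature streams; the exact
insertion points inside the neck are an architecture concern outside
this library's scope.  Untrained parameters for analysis are drawn
deterministically from U[-0.1, 0.1] under a seed.

This is a NumPy implementation (convolution via
`scipy.signal.correlate`, the conv-layer cross-correlation
convention); it is a reference/analysis implementation, not a
trainable module.

## Augmentation

All geometric transforms remap each box through the exact pixel
mapping, take the axis-aligned hull of the four transformed corners
where the mapping is not axis-preserving (rotation, affine), then
clip to the output viewport and drop slivers: clipped area below
`min_box_area_px` (default 4) or either side below 2 px.  Photometric
transforms (grayscale, color dithering) never touch labels.  Class
ids are never changed by any operator.

* **Mosaic / Mosaic-9**: 2x2 (resp. 3x3) grid over the output canvas;
  the interior boundaries are jittered uniformly by +-jitter x
  out_size around the even grid (clamped so every cell keeps at least
  one pixel), each source is resized cell-filling (aspect-free), and
  its labels follow the same per-cell affine.  With zero jitter the
  tiles partition the canvas exactly.  The published description of
  the 9-image rule stops at "specific rules"; this grid realization
  is the deterministic choice made here.
* **Mixup**: pixels = lambda a + (1 - lambda) b in float, quantized
  round-half-up to 8 bits; labels are the union (concatenation) of
  both lists.  lambda ~ Beta(alpha, alpha) with alpha = 8 (tight
  around 0.5) unless `fixed_lambda` is set; no mixing law is
  published, and union labeling is the standard detection-mixup
  convention.  Execution probabilities (mosaic 1.0, mixup 0.5) are
  pipeline configuration, not operator state.
* **Static kinds**: scaling, grayscale, center/random crop, random
  crop with rescale, edge padding, rotation, horizontal/vertical
  flip, color dithering, affine.  The source description counts "12
  methods" but names these eleven; the registry carries the named
  ones.  Rotation uses the counterclockwise convention of
  `PIL.Image.rotate` with canvas expansion; the forward corner map
  used for labels was verified against pixel provenance.

Every operator is a pure function of (inputs, config, seed); the
suite asserts bitwise determinism.

## Anchor optimization

One (w, h) pair per labeled box is clustered by Lloyd's algorithm
with k-means++ seeding, k = 9.  The default distance is
1 - IoU(box, center) with both boxes co-anchored at the origin (the
YOLO-family convention, scale-aware in the way detector matching is);
squared-euclidean is available for comparison.  Centers update as
member means; empty clusters re-seed to the farthest point;
convergence at max center movement < 1e-6 or 300 iterations.  Ten
k-means++ restarts are run and the lowest final objective wins — a
single seeding can land in a visibly wrong local optimum even on
well-separated data.  Because the mean minimizes the squared-
euclidean objective but not the 1-IoU one, a Lloyd step can in rare
cases raise the 1-IoU objective; the iteration then reverts that step
and stops, so the recorded objective trace is non-increasing by
construction.  The nine centers are sorted by area and grouped into
three triplets (small/medium/large detection scales).  Dimensions are
taken at native annotation resolution; the resolution used for the
published clustering is unstated, so no rescaling is applied unless
requested.

The nine published anchors for the passion-fruit pest dataset appear
in tests and the acceptance script only as planted cluster centers
and as a grouping example — recovering them from the real dataset
would require that dataset.

## Evaluation

Greedy per-class, per-image matching: detections sorted by descending
confidence (stable sort, so confidence ties break by input order),
each matched to the unmatched ground truth of highest IoU at or above
the threshold (default 0.5, PASCAL-style; the published work does not
state its threshold).  AP is the area under the monotone
non-increasing precision envelope over recall (all-point
interpolation — the "area under the P-R curve" reading, not the
11-point variant); mAP averages per-class APs; F1 = 2PR/(P+R) at a
confidence cutoff (default 0.25); mDT is the mean per-image detection
time in seconds and is reported only when timings are supplied.  A
class with no ground truth but detections has AP 0.  The
implementation's vectorized envelope is tested to 1e-9 against an
O(n^2) definition-level sweep on hundreds of random instances.

## Synthetic data

The scene generator renders colored ellipses on a smooth random
texture, one label per ellipse, placed without overlap by rejection
sampling (bounded retries; on packing failure the scene carries fewer
objects, logged).  The size law is a (0.8, 0.15, 0.05) mixture over
small/medium/large side ranges ((8-31), (40-96), (100-200) px,
clamped to the image), so at least ~80% of boxes fall under the
32 x 32 px small-object cutoff (COCO convention) — matching the
small-object-heavy profile of field pest datasets.  Classes default
to uniform over the 12-class registry.

What the scenes do *not* emulate: real pest appearance and texture,
occlusion, lighting variation, annotation noise, or the per-class
imbalance of a real collection.  Passing tests therefore certify the
geometry, bookkeeping and statistics of the implementations — not
detection difficulty on real imagery.

The planted evaluation fixture inverts the evaluator: given per-class
TP/FP flag sequences it constructs geometry (TP = exact copy of the
next unmatched ground truth, FP = far-away box, strictly decreasing
confidences) such that greedy matching at IoU 0.5 reproduces the
flags, and stamps the analytically implied AP alongside.  The fixture
is self-verifying: the evaluation stack must reproduce both.

## Dataset I/O and split

VOC 2007 XML is read and written in the LabelImg dialect; corner
coordinates are used verbatim as continuous values.  Malformed
objects (missing fields, inverted boxes, names outside the 12-class
registry) are rejected with file and object context.  YOLO txt
labels convert exactly between normalized center/size and corner
pixels; round-tripping through the 6-decimal text format is accurate
to half a pixel per corner.

The split procedure shuffles ids under a seed, holds out 2/10 for
testing, and divides the remaining 8/10 in a 7:3 ratio into train and
validation — final fractions 0.56/0.24/0.20, realized with
largest-remainder rounding (ties resolved train, val, test) so the
three parts always partition the input: 6,000 ids give
3,360/1,440/1,200.  The split is a global random partition, not
stratified per class.

## Problem sizes and numerical conventions

Tests and the acceptance script run oracle comparisons at a few
hundred random instances per property, planted-recovery clustering at
900 points, and scenes at 96-320 px — sizes chosen so the full suite
exercises every code path in seconds while keeping binomial
tolerances comfortable (e.g. the >= 70% small-object check at 1,000
boxes under an 80% generator weight).  Key tolerances: IoU vs
rasterization 1e-9; penalty vs sampled-line oracle 1e-6; analytic vs
finite-difference gradient 1e-4 relative; AP vs brute-force sweep
1e-9; planted anchor recovery within 2 px.

## Known limitations

* CBAM here is inference-only NumPy; no training, and no claim about
  attention quality with untrained weights.
* The published headline detection metrics (mAP, F1, mDT of the
  trained detector) require the authors' dataset and GPU training and
  are not reproduced by this package.
* Rotation and affine label remapping return the axis-aligned hull of
  transformed corners, which over-covers rotated objects — inherent
  to axis-aligned annotation.
* The 1-IoU K-means objective is optimized heuristically (mean
  updates with a monotonicity safeguard); it is the field convention,
  not an exact minimizer.
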