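# Methods

This note documents the models, conventions and numerical choices behind
`microdet`, in the order data flows through the pipeline.

## Coordinate conventions

Genomic intervals are 0-based half-open (`[start, end)`, the BED
convention) everywhere; BED output therefore needs no shifting.  Pixel
boxes are half-open on both axes with the origin at the top-left corner.
A single convention at every boundary removes the usual off-by-one error
class between rendering, annotation and calling.

## Fragment-view rendering and the pixel ↔ genomic map

A fragment view draws each complex as one row of filled bars, rows stacked
top-to-bottom grouped by cluster, with a fixed gap between cluster bands.
The stacking order is `(cluster, leftmost fragment start, complex id)` —
any consistent order works for detection; this one is deterministic.
Unclustered complexes form a residual group drawn last, mirroring how
un-clustered complexes appear as a trailing band in clustered views.

The x mapping over the plot area `[plot_x0, plot_x1)` is

```
px(g) = plot_x0 + floor((g − region.start) / L · W)
```

with `L` the region length and `W` the plot width.  Floor plus half-open
intervals makes adjacent genomic intervals tile into adjacent,
non-overlapping pixel runs.  Fragments narrower than one pixel are drawn
one pixel wide.  Axis decorations (baseline, ticks) are drawn only in the
bottom margin, so the map stays affine — and invertible — over the plot
area.  The inverse transform rounds half-up; each recovered endpoint is
therefore within one pixel's genomic width (`⌈L / W⌉` bp) of the truth,
a bound the test suite checks over random geometries.

Every rendered PNG gets a JSON sidecar (`<image>.map.json`) holding the
region, the plot-area bounds, the row order and the per-cluster pixel
bands — the machine-readable replacement for keeping genomic coordinates
"next to" an image.

Rendering is byte-deterministic: same inputs, same PNG bytes.  Text is
deliberately absent from the figures (font rasterisation is
platform-dependent); ticks are plain lines.

## Synthetic data

The generator plants `n_domains` disjoint intervals in the region, with a
minimum gap, by a constructive stars-and-bars scheme: domain lengths are
drawn uniformly from `domain_length_range`, and the leftover slack is split
into random extra gaps, so every feasible configuration is reachable and
infeasible packings fail fast.  Each domain receives
`complexes_per_domain` complexes whose fragments (uniform count, uniform
length, uniform placement) never cross the domain boundary; the domain
index is the cluster label.  Background complexes — count
`round(f · n_signal / (1 − f))` so they form fraction `f` of the total —
have fragments uniform over the whole region and carry a distinct
trailing cluster label.

Defaults describe a realistic mid-size scenario: a ~200 kb *Drosophila*
chr2R window, three 15–40 kb domains separated by ≥8 kb, 25 complexes per
domain with 3–8 fragments of 0.5–3 kb, 10% background.  All draws flow
from one seed; `make_dataset` derives image *i*'s seed as `base + i`, so a
corpus regenerates byte-identically.

What the generator does *not* emulate: real ChIA-Drop fragments-per-GEM
and coverage distributions, fuzzy or nested domain boundaries, partially
mis-clustered complexes, and inter-domain contacts.  Synthetic domains
are visually crisper than real clustered views, so passing the recovery
gate here demonstrates that the pipeline's machinery is correct and
trainable — not that the tiny default backbone matches performance on
real data, which has only been approached with far longer training runs
on manually annotated views.

## The detector

The detector follows the two-stage Faster R-CNN contract, implemented
compactly for CPU:

* **Preprocessing** rescales each image so its short side hits
  `target_short_side_px` (default 240), scaling and, if necessary,
  clipping the annotation boxes with the same factor.  Detections are
  reported back in original pixel coordinates.
* **Backbone** ("tiny", fixed, not learned): the image is reduced to an
  ink map (1 − min RGB/255, so saturated bars score high on a white
  background) and pooled into stride-8 cells with five channels — mean
  ink, max ink, occupancy, mean |∂y|, mean |∂x|.
* **RPN**: a learned 3×3 convolution (im2col + dense layer, 32 hidden
  units, ReLU) over the feature map with sibling 1×1 classification and
  regression layers, scoring 9 anchors per cell (scales 24/48/96 px ×
  aspect ratios 0.5/1/2, centred on cell centres so the grid evenly
  covers the image).  Anchors with IoU ≥ 0.7 against any ground-truth box
  are positive, < 0.3 negative, the rest ignored; the best anchor per
  ground truth is always positive so every domain owns at least one.  Per
  image a balanced sample of up to 128 anchors yields the softmax
  cross-entropy classification loss and the smooth-L1 regression loss on
  the standard (tx, ty, tw, th) parameterisation.
* **Proposals**: decoded anchor boxes, clipped, filtered for minimum
  size, NMS at IoU 0.7, top-24 during training (ground-truth boxes
  appended so the heads always see true positives), top-40 at inference.
* **RoI pooling**: each proposal (and a 50%-dilated context copy, which
  lets the regressor see where the ink ends) is max-pooled to a 4×4 grid
  per channel and flattened.
* **Detector heads**: one dense hidden layer (64 units, ReLU) with
  softmax classification (background/micro-domain) and box-regression
  outputs; RoIs with IoU ≥ 0.5 against ground truth are foreground; a
  balanced minibatch of 64 RoIs per image yields the detector losses.
* **Optimisation**: per-image Adam steps (lr 0.005); all randomness
  (initialisation, anchor/RoI sampling, image order) flows from
  `config.seed`.

Per epoch the four loss components are averaged over images and logged;
by construction every record satisfies exactly

```
rpn_loss      = loss_rpn_regression + loss_rpn_classifier
fastrcnn_loss = loss_detector_classifier + loss_detector_regression
total_loss    = rpn_loss + fastrcnn_loss
```

**Checkpoint rule**: a checkpoint is kept whenever the epoch's total loss
is smaller than the running mean of all previous epochs' totals.  The
first epoch has no predecessors; the empty mean is taken as +∞, so epoch
one is always checkpointed and a final artifact always exists.  The final
model is the last checkpoint.  Artifacts round-trip as a weights `.npz`,
a JSON config and a loss-history CSV; loading verifies that weight shapes
and config agree.

**Inference** is deterministic: proposals → head scores → decoded boxes →
score threshold (default 0.7) → class-wise NMS (IoU 0.5) → rescale to
original coordinates.

## Merging and coordinate transforming

Duplicate detections of one domain share a cluster band, i.e. nearly the
same vertical extent, so merging keys on **vIoU** — the interval IoU of
the two boxes' y-axis projections — with threshold 0.8.  An *additional
x-overlap requirement* prevents two distinct domains that share a band
from fusing.  (The y-projection reading of "vertical IoU" is a documented
interpretation, isolated in one function.)

Linking is transitive (connected components, not greedy pairwise) for
order-independence, and the component collapse is *iterated to a fixed
point*: componentwise bounding boxes can newly satisfy the link predicate
even when no original pair did, and a single pass would then not be
idempotent.  Merging is contractive, idempotent and deterministic; each
merged detection keeps the component's maximum score.

Merged boxes are clipped to the plot area and their left/right edges
inverted through the render map (round half-up) to produce genomic calls,
written as BED6 with scores scaled to 0–1000.

## Evaluation

* `pixel_iou` / `giou` / `viou` use half-open discrete counting and are
  tested against brute-force pixel/base/row-set oracles.
* Matching is greedy one-to-one, highest score first, ties broken by
  leftmost box; pixel-space matching counts a pair at IoU ≥ 0.5 (the
  conventional detection threshold), genomic matching at gIoU > 0 (a
  domain counts as detected if the call overlaps it at all; the reported
  per-domain gIoU then quantifies how well).
* AP uses all-point interpolation (area under the precision envelope);
  with one class, mAP = AP.
* ROC negatives: a detection task has no true negatives, so the ROC is
  built over the detections themselves, TP vs FP, sweeping the score
  threshold; AUROC is the trapezoidal area and equals the Mann–Whitney
  pair statistic.  `accuracy` = TP/(TP+FP+FN) for the same reason.
* k-fold splitting shuffles with a seeded generator; fold sizes differ by
  at most one.

## Problem sizes

The bundled experiments use 480×240 px images, 25-image corpora (20
train / 5 held out), 60 training epochs, and 200-region round-trip
sweeps — sizes chosen so the full test suite and the acceptance script
each run in a few minutes on a single CPU core while still exercising
every stage end to end.  Under these conditions the held-out recovery is
mean gIoU ≈ 0.84–0.87 with recall 1.0 (see `scripts/acceptance.py`
output), comfortably above the ≥ 0.5 gate asserted in the test suite.

## Known limitations

* The tiny fixed backbone is tuned to fragment views (bars on a light
  background); arbitrary natural images would need a learned backbone
  behind the same `backbone` config switch.
* Single category only ("m" = micro-domain); no multi-class heads.
* No sub-pixel box refinement; boundary precision is limited to one
  pixel's genomic width by construction.
* Complex clustering is an input (or comes from the generator); the
  package does not cluster complexes itself.
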