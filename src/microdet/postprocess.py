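"""Detection post-processing: vIoU merging and pixel-to-genomic transform.

Duplicate detections of one micro-domain typically share the same cluster
band, i.e. nearly the same vertical extent.  Merging therefore keys on the
vertical IoU (IoU of the boxes' projections onto the y axis, threshold
0.8) with an additional x-overlap requirement so two distinct domains that
happen to share a band are never fused.  Merged boxes are then transformed
to genomic intervals through the render map's inverse x mapping.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .render import RenderMap
from .types import Detection, GenomicInterval, MicroDomainCall, PixelBox

DEFAULT_VIOU_THRESHOLD = 0.8


def viou(a: PixelBox, b: PixelBox) -> float:
    """Vertical IoU: interval IoU of the two boxes' y-axis projections."""
    inter = max(0, min(a.y2, b.y2) - max(a.y1, b.y1))
    union = (a.y2 - a.y1) + (b.y2 - b.y1) - inter
    return inter / union if union > 0 else 0.0


def _x_overlap(a: PixelBox, b: PixelBox) -> bool:
    return a.x1 < b.x2 and b.x1 < a.x2


def _bounding(boxes: Sequence[PixelBox]) -> PixelBox:
    return PixelBox(
        min(b.x1 for b in boxes),
        min(b.y1 for b in boxes),
        max(b.x2 for b in boxes),
        max(b.y2 for b in boxes),
    )


def _components_once(boxes: Sequence[PixelBox], viou_threshold: float) -> list[list[int]]:
    """One round of connected components (edges: viou > thr, x overlap)."""
    n = len(boxes)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (
                viou(boxes[i], boxes[j]) > viou_threshold
                and _x_overlap(boxes[i], boxes[j])
            ):
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    comps: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        comps[lab].append(i)
    return comps


def _merge_components(
    dets: Sequence[Detection], viou_threshold: float
) -> list[list[int]]:
    """Grouping of duplicate detections, iterated to a fixed point.

    Each round links detections whose boxes have viou > threshold and
    overlapping x-ranges, takes connected components, and replaces every
    component by its bounding box; rounds repeat until no component
    shrinks the set further.  Iterating matters because two merged
    bounding boxes can overlap even when no original pair did; the fixed
    point makes the merge idempotent and order-independent.
    """
    if not dets:
        return []
    groups: list[list[int]] = [[i] for i in range(len(dets))]
    boxes: list[PixelBox] = [d.box for d in dets]
    while True:
        comps = _components_once(boxes, viou_threshold)
        if len(comps) == len(groups):
            return groups
        groups = [[i for g in comp for i in groups[g]] for comp in comps]
        boxes = [_bounding([boxes[g] for g in comp]) for comp in comps]


def merge_detections(
    dets: Sequence[Detection],
    viou_threshold: float = DEFAULT_VIOU_THRESHOLD,
) -> list[Detection]:
    """Merge duplicate detections of one domain area.

    Each connected component (vIoU > threshold and overlapping x-ranges,
    closed transitively and iterated to a fixed point) collapses to its
    componentwise bounding box with the component's maximum score.
    Output is sorted by x1.  Idempotent.
    """
    categories = {d.category for d in dets}
    if len(categories) > 1:
        raise ValueError(f"mixed detection categories: {sorted(categories)}")
    merged: list[Detection] = []
    for comp in _merge_components(dets, viou_threshold):
        boxes = [dets[i].box for i in comp]
        merged.append(
            Detection(
                PixelBox(
                    min(b.x1 for b in boxes),
                    min(b.y1 for b in boxes),
                    max(b.x2 for b in boxes),
                    max(b.y2 for b in boxes),
                ),
                max(dets[i].score for i in comp),
                dets[comp[0]].category,
            )
        )
    return sorted(merged, key=lambda d: (d.box.x1, d.box.y1))


def box_to_genomic(box: PixelBox, rmap: RenderMap) -> GenomicInterval:
    """Transform a pixel box's left/right edges into a genomic interval.

    The box is clipped to the plot area's x bounds first; each endpoint is
    the inverse of the render ``px`` map with round-half-up, so the
    per-endpoint error is at most one pixel's genomic width.
    """
    if box.x2 <= rmap.plot_x0 or box.x1 >= rmap.plot_x1:
        raise ValueError(
            f"box x-range [{box.x1}, {box.x2}) entirely outside plot area "
            f"[{rmap.plot_x0}, {rmap.plot_x1})"
        )
    x1 = max(box.x1, rmap.plot_x0)
    x2 = min(box.x2, rmap.plot_x1)
    start = rmap.genomic(x1)
    end = rmap.genomic(x2)
    if end <= start:  # sub-pixel-wide box: keep a 1 bp interval
        end = min(start + 1, rmap.region.end)
        start = end - 1
    return GenomicInterval(rmap.region.chrom, start, end)


def calls_from_detections(
    dets: Sequence[Detection],
    rmap: RenderMap,
    viou_threshold: float = DEFAULT_VIOU_THRESHOLD,
) -> list[MicroDomainCall]:
    """Merge detections, then transform each merged box to a genomic call."""
    calls: list[MicroDomainCall] = []
    for comp in _merge_components(dets, viou_threshold):
        boxes = [dets[i].box for i in comp]
        bbox = PixelBox(
            min(b.x1 for b in boxes),
            min(b.y1 for b in boxes),
            max(b.x2 for b in boxes),
            max(b.y2 for b in boxes),
        )
        calls.append(
            MicroDomainCall(
                box_to_genomic(bbox, rmap),
                max(dets[i].score for i in comp),
                tuple(boxes),
            )
        )
    return sorted(calls, key=lambda c: c.interval.start)
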