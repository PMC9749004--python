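"""Vectorised box arithmetic: anchors, IoU, delta coding, NMS.

Boxes are float arrays of shape (N, 4) as (x1, y1, x2, y2), half-open.
Deltas use the standard Faster R-CNN parameterisation
(tx, ty, tw, th) = ((gx-ax)/aw, (gy-ay)/ah, log(gw/aw), log(gh/ah)).
"""

from __future__ import annotations

import numpy as np

# clamp on tw/th before exp so a wild early regression cannot overflow
MAX_LOG_SCALE = 4.0


def generate_anchors(
    feat_h: int,
    feat_w: int,
    stride: int,
    scales: tuple[int, ...],
    ratios: tuple[float, ...],
) -> np.ndarray:
    """Dense anchor grid covering the image evenly.

    One anchor per (cell, scale, ratio) centred on the cell centre; ratio
    is height/width, so ``w = scale/sqrt(r)``, ``h = scale*sqrt(r)``.
    Returned flattened position-major: shape (feat_h*feat_w*A, 4).
    """
    ws, hs = [], []
    for s in scales:
        for r in ratios:
            ws.append(s / np.sqrt(r))
            hs.append(s * np.sqrt(r))
    ws = np.array(ws)
    hs = np.array(hs)
    cx = (np.arange(feat_w) + 0.5) * stride
    cy = (np.arange(feat_h) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (H*W, 2)
    anchors = np.empty((centers.shape[0], ws.size, 4))
    anchors[:, :, 0] = centers[:, [0]] - ws / 2
    anchors[:, :, 1] = centers[:, [1]] - hs / 2
    anchors[:, :, 2] = centers[:, [0]] + ws / 2
    anchors[:, :, 3] = centers[:, [1]] + hs / 2
    return anchors.reshape(-1, 4)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between box sets a (N,4) and b (M,4)."""
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    iw = np.clip(ix2 - ix1, 0, None)
    ih = np.clip(iy2 - iy1, 0, None)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def encode_deltas(gt: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Regression targets taking each anchor onto its ground-truth box."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack(
        [
            (gcx - acx) / aw,
            (gcy - acy) / ah,
            np.log(gw / aw),
            np.log(gh / ah),
        ],
        axis=1,
    )


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Apply predicted deltas to anchors, producing boxes."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = acx + deltas[:, 0] * aw
    cy = acy + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -MAX_LOG_SCALE, MAX_LOG_SCALE))
    h = ah * np.exp(np.clip(deltas[:, 3], -MAX_LOG_SCALE, MAX_LOG_SCALE))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_boxes(boxes: np.ndarray, width: int, height: int) -> np.ndarray:
    out = boxes.copy()
    out[:, 0] = np.clip(out[:, 0], 0, width)
    out[:, 1] = np.clip(out[:, 1], 0, height)
    out[:, 2] = np.clip(out[:, 2], 0, width)
    out[:, 3] = np.clip(out[:, 3], 0, height)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices.

    Ordering is deterministic: descending score with ties broken by x1
    then y1.
    """
    if boxes.shape[0] == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((boxes[:, 1], boxes[:, 0], -scores))
    keep: list[int] = []
    suppressed = np.zeros(boxes.shape[0], dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(int(idx))
        ious = iou_matrix(boxes[[idx]], boxes[order]).ravel()
        suppressed[order[ious > iou_threshold]] = True
        suppressed[idx] = True
    return np.array(keep, dtype=int)
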