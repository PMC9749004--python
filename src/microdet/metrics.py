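"""Evaluation statistics for micro-domain detection.

Pixel IoU and genomic IoU (gIoU) quantify box/interval agreement; greedy
one-to-one matching types detections as TP/FP and truths as FN; from the
matched sets come precision/recall/F1, the P-R curve with its all-point
interpolated average precision (single class, so mAP = AP), and a ROC
curve whose negatives are the false-positive detections (a detection task
has no true negatives; this convention is documented in the methods note).
"accuracy" is TP / (TP + FP + FN) for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .types import Detection, GenomicInterval, MicroDomainCall, PixelBox, sort_detections

DEFAULT_IOU_THRESHOLD = 0.5


def pixel_iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection over union of two pixel boxes (half-open counting)."""
    iw = max(0, min(a.x2, b.x2) - max(a.x1, b.x1))
    ih = max(0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def giou(a: GenomicInterval, b: GenomicInterval) -> float:
    """Genomic IoU: overlap length over union length; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = a.length + b.length - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """One-to-one assignment between detections and ground truths."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    fp: list[int] = field(default_factory=list)
    fn: list[int] = field(default_factory=list)


@dataclass
class EvalReport:
    """Summary of a detection evaluation run.

    ``accuracy`` is TP/(TP+FP+FN); ``auroc``/``map`` are None when the
    report was built from genomic calls only.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    per_domain_giou: list[float] = field(default_factory=list)
    mean_giou: float = 0.0
    auroc: Optional[float] = None
    map: Optional[float] = None
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    def summary(self) -> str:
        lines = [
            "Micro-domain evaluation",
            "-" * 34,
            f"{'TP / FP / FN':<18}{self.tp} / {self.fp} / {self.fn}",
            f"{'precision':<18}{self.precision:.3f}",
            f"{'recall':<18}{self.recall:.3f}",
            f"{'F1':<18}{self.f1:.3f}",
            f"{'accuracy':<18}{self.accuracy:.3f}",
            f"{'mean gIoU':<18}{self.mean_giou:.3f}",
        ]
        if self.auroc is not None:
            lines.append(f"{'AUROC':<18}{self.auroc:.3f}")
        if self.map is not None:
            lines.append(f"{'mAP':<18}{self.map:.3f}")
        return "\n".join(lines)


def match_detections(
    dets: Sequence[Detection],
    truths: Sequence[PixelBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching, highest-score detection first.

    A detection pairs with the unmatched truth of highest IoU provided
    that IoU >= threshold.  Score ties break by leftmost box.
    Indices refer to the input order of ``dets``/``truths``.
    """
    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].score, dets[i].box.x1, dets[i].box.y1),
    )
    result = MatchResult()
    used = [False] * len(truths)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if used[j]:
                continue
            v = pixel_iou(dets[i].box, t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            used[best_j] = True
            result.pairs.append((i, best_j))
        else:
            result.fp.append(i)
    result.fn = [j for j, u in enumerate(used) if not u]
    return result


def _tp_labels(
    dets: Sequence[Detection],
    truths: Sequence[PixelBox],
    iou_threshold: float,
) -> tuple[list[Detection], np.ndarray]:
    """Detections in score order with a TP(1)/FP(0) label each."""
    ordered = sort_detections(dets)
    match = match_detections(ordered, truths, iou_threshold)
    paired = {i for i, _ in match.pairs}
    labels = np.array([1 if i in paired else 0 for i in range(len(ordered))])
    return ordered, labels


def pr_curve_and_map(
    dets: Sequence[Detection],
    truths: Sequence[PixelBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall sweep and all-point interpolated AP.

    Detections are swept in descending score; after each, precision and
    recall are recorded.  AP integrates the precision envelope over recall
    (all-point interpolation).  With a single class, mAP = AP.
    """
    if not truths:
        raise ValueError("cannot compute a P-R curve with no ground truths")
    ordered, labels = _tp_labels(dets, truths, iou_threshold)
    if not ordered:
        return [], 0.0
    tp_cum = np.cumsum(labels)
    ranks = np.arange(1, len(ordered) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / len(truths)
    points = list(zip(recall.tolist(), precision.tolist()))
    # precision envelope: max precision at any recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return points, float(ap)


def roc_and_auroc(
    dets: Sequence[Detection],
    truths: Sequence[PixelBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[list[tuple[float, float]], float]:
    """ROC over detection scores, TP detections vs FP detections.

    Every detection is typed TP or FP by matching against truth; sweeping
    the score threshold then yields (FPR, TPR) points and the trapezoidal
    AUROC.  Requires at least one of each label.
    """
    ordered, labels = _tp_labels(dets, truths, iou_threshold)
    if len(set(labels.tolist())) < 2:
        raise ValueError(
            "ROC undefined: detections are all one class (all TP or all FP)"
        )
    scores = np.array([d.score for d in ordered])
    fpr, tpr, _ = roc_curve(labels, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auroc


def evaluate_calls(
    calls: Sequence[MicroDomainCall],
    truth_intervals: Sequence[GenomicInterval],
) -> EvalReport:
    """Genomic evaluation: greedy gIoU matching of calls against truths.

    A call counts as detecting a truth when their gIoU exceeds 0.  The
    report carries per-matched-domain gIoU, the mean over matched pairs,
    and precision/recall/F1/accuracy from the TP/FP/FN counts.
    """
    if not truth_intervals:
        raise ValueError("cannot evaluate against an empty truth set")
    order = sorted(
        range(len(calls)),
        key=lambda i: (-calls[i].score, calls[i].interval.start),
    )
    used = [False] * len(truth_intervals)
    per_domain: list[float] = []
    tp = fp = 0
    for i in order:
        best_j, best_g = -1, 0.0
        for j, t in enumerate(truth_intervals):
            if used[j]:
                continue
            g = giou(calls[i].interval, t)
            if g > best_g:
                best_j, best_g = j, g
        if best_j >= 0 and best_g > 0.0:
            used[best_j] = True
            per_domain.append(best_g)
            tp += 1
        else:
            fp += 1
    fn = used.count(False)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    mean_giou = float(np.mean(per_domain)) if per_domain else 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        per_domain_giou=per_domain,
        mean_giou=mean_giou,
        tp=tp,
        fp=fp,
        fn=fn,
    )


def kfold_split(items: Sequence, k: int, seed: int) -> list[list]:
    """Split items into k shuffled folds whose sizes differ by at most 1."""
    if k < 1 or k > max(len(items), 1):
        raise ValueError(f"k must be in [1, {len(items)}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        folds[pos % k].append(items[int(idx)])
    return folds
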