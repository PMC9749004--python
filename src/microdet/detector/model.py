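"""Training and inference for the two-stage fragment-view detector.

Training follows the classic two-stage recipe, per image and per epoch:

1. the fixed backbone turns the rescaled image into a feature map;
2. the RPN (a 3x3 convolution with sibling classification/regression
   layers) scores a dense anchor grid; anchors are labelled
   foreground/background by IoU against ground truth, a sampled anchor
   minibatch yields ``loss_rpn_classifier`` (softmax cross-entropy) and
   ``loss_rpn_regression`` (smooth-L1 on positives);
3. RPN proposals (decoded, clipped, NMS'd, ground truth appended) are
   RoI-pooled to a fixed-size feature map and passed through fully
   connected heads, yielding ``loss_detector_classifier`` and
   ``loss_detector_regression`` on a sampled RoI minibatch.

The loss identities ``rpn_loss = loss_rpn_regression + loss_rpn_classifier``,
``fastrcnn_loss = loss_detector_classifier + loss_detector_regression`` and
``total_loss = rpn_loss + fastrcnn_loss`` hold exactly on every record.
A checkpoint is written whenever an epoch's total loss drops below the
running mean of all previous epochs' totals; the final artifact is the
last checkpoint.
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

from ..types import Annotation, Detection, PixelBox
from .boxes import (
    clip_boxes,
    decode_deltas,
    encode_deltas,
    generate_anchors,
    iou_matrix,
    nms,
)
from .config import DetectorConfig
from .features import get_backbone, im2col3x3
from .net import Dense, relu, relu_grad, smooth_l1, softmax, softmax_cross_entropy

logger = logging.getLogger(__name__)

ImageLike = Union[str, Path, Image.Image, np.ndarray]

WEIGHTS_FILE = "model_weights.npz"
CONFIG_FILE = "config.json"
HISTORY_FILE = "loss_history.csv"

HISTORY_COLUMNS = [
    "epoch",
    "loss_rpn_classifier",
    "loss_rpn_regression",
    "loss_detector_classifier",
    "loss_detector_regression",
    "rpn_loss",
    "fastrcnn_loss",
    "total_loss",
    "rpn_classifier_accuracy",
]


def _load_image(image: ImageLike) -> np.ndarray:
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            return np.asarray(im.convert("RGB"))
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


# ---------------------------------------------------------------------------
# loss records and the checkpoint rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossRecord:
    """Per-epoch loss decomposition; the three sum identities are exact."""

    epoch: int
    loss_rpn_classifier: float
    loss_rpn_regression: float
    loss_detector_classifier: float
    loss_detector_regression: float
    rpn_loss: float
    fastrcnn_loss: float
    total_loss: float
    rpn_classifier_accuracy: float

    @classmethod
    def from_components(
        cls,
        epoch: int,
        loss_rpn_classifier: float,
        loss_rpn_regression: float,
        loss_detector_classifier: float,
        loss_detector_regression: float,
        rpn_classifier_accuracy: float,
    ) -> "LossRecord":
        rpn_loss = loss_rpn_regression + loss_rpn_classifier
        fastrcnn_loss = loss_detector_classifier + loss_detector_regression
        return cls(
            epoch=epoch,
            loss_rpn_classifier=loss_rpn_classifier,
            loss_rpn_regression=loss_rpn_regression,
            loss_detector_classifier=loss_detector_classifier,
            loss_detector_regression=loss_detector_regression,
            rpn_loss=rpn_loss,
            fastrcnn_loss=fastrcnn_loss,
            total_loss=rpn_loss + fastrcnn_loss,
            rpn_classifier_accuracy=rpn_classifier_accuracy,
        )


def checkpoint_epochs(total_losses: Sequence[float]) -> list[int]:
    """Epochs (1-based) at which a checkpoint is saved.

    Epoch ``e`` is checkpointed iff its total loss is smaller than the
    running mean of all previous epochs' totals; the first epoch has no
    predecessors (empty mean treated as +inf) and is always checkpointed.
    """
    saved: list[int] = []
    for e, loss in enumerate(total_losses, start=1):
        prior = total_losses[: e - 1]
        if not prior or loss < float(np.mean(prior)):
            saved.append(e)
    return saved


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    image: ImageLike,
    annotations: Sequence[Annotation],
    config: DetectorConfig,
) -> tuple[np.ndarray, list[Annotation], float]:
    """Rescale an image so its short side hits the configured size, and
    scale (and if needed clip) every annotation box accordingly.

    Returns ``(scaled image, scaled annotations, scale factor)``; the
    factor maps original to scaled coordinates, so detections divide by
    it to get back.
    """
    arr = _load_image(image)
    h, w = arr.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("degenerate image")
    scale = config.target_short_side_px / min(h, w)
    if scale != 1.0:
        new_w = max(int(round(w * scale)), 1)
        new_h = max(int(round(h * scale)), 1)
        arr = np.asarray(
            Image.fromarray(arr).resize((new_w, new_h), Image.BILINEAR)
        )
    else:
        new_w, new_h = w, h
    scaled: list[Annotation] = []
    for ann in annotations:
        b = ann.box
        x1, y1 = max(b.x1, 0), max(b.y1, 0)
        x2, y2 = min(b.x2, w), min(b.y2, h)
        if (x1, y1, x2, y2) != b.as_tuple():
            logger.warning(
                "clipping box %s to image bounds %dx%d", b.as_tuple(), w, h
            )
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"box {b.as_tuple()} lies outside the image")
        sx1 = int(round(x1 * scale))
        sy1 = int(round(y1 * scale))
        sx2 = max(int(round(x2 * scale)), sx1 + 1)
        sy2 = max(int(round(y2 * scale)), sy1 + 1)
        sx2, sy2 = min(sx2, new_w), min(sy2, new_h)
        scaled.append(
            Annotation(ann.image_path, PixelBox(sx1, sy1, sx2, sy2), ann.category)
        )
    return arr, scaled, scale


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class _ImageTensors:
    """Per-image quantities that do not change across epochs."""

    feat: np.ndarray          # (Hf, Wf, C) backbone features
    patches: np.ndarray       # (Hf*Wf, 9C) im2col RPN input
    anchors: np.ndarray       # (Hf*Wf*A, 4)
    gt_boxes: np.ndarray      # (G, 4) in scaled coords
    anchor_labels: np.ndarray  # 1 fg / 0 bg / -1 ignore
    anchor_targets: np.ndarray  # (N, 4) deltas to matched gt
    size: tuple[int, int]     # (w, h) of the scaled image


class FragmentViewDetector:
    """Two-stage micro-domain detector over fragment-view images.

    Built from a dataset of ``(image, annotations)`` pairs plus a
    :class:`DetectorConfig`; ``fit()`` runs the training loop and returns
    a :class:`TrainingResults`.
    """

    def __init__(
        self,
        dataset: Sequence[tuple[ImageLike, Sequence[Annotation]]],
        config: Optional[DetectorConfig] = None,
    ):
        self.config = config or DetectorConfig()
        if not dataset:
            raise ValueError("training requires at least one annotated image")
        categories = {a.category for _, anns in dataset for a in anns}
        if not categories:
            raise ValueError("training requires at least one annotation")
        if len(categories) > 1:
            raise ValueError(f"single-category detector, got {sorted(categories)}")
        self.category = categories.pop()
        self._dataset = [(img, list(anns)) for img, anns in dataset]
        self._rng = np.random.default_rng(self.config.seed)
        self._backbone, self._n_channels = get_backbone(self.config.backbone)
        self._build_layers()

    @classmethod
    def from_corpus(
        cls,
        corpus_dir: str | Path,
        config: Optional[DetectorConfig] = None,
        image_names: Optional[Sequence[str]] = None,
    ) -> "FragmentViewDetector":
        """Build from a directory holding images plus ``annotations.csv``."""
        from ..io_formats import read_annotation_table

        corpus_dir = Path(corpus_dir)
        annotations = read_annotation_table(corpus_dir / "annotations.csv")
        by_image: dict[str, list[Annotation]] = {}
        for ann in annotations:
            by_image.setdefault(ann.image_path, []).append(ann)
        names = image_names if image_names is not None else sorted(by_image)
        dataset = [(corpus_dir / name, by_image[name]) for name in names]
        return cls(dataset, config)

    # -- network ------------------------------------------------------------

    def _build_layers(self) -> None:
        cfg = self.config
        A = cfg.anchors_per_cell
        c = self._n_channels
        pool_dim = 2 * c * cfg.roi_pool_size**2
        rng = self._rng
        self.layers: dict[str, Dense] = {
            "rpn_hidden": Dense(rng, 9 * c, cfg.rpn_hidden_units),
            "rpn_cls": Dense(rng, cfg.rpn_hidden_units, 2 * A),
            "rpn_reg": Dense(rng, cfg.rpn_hidden_units, 4 * A),
            "head_fc": Dense(rng, pool_dim, cfg.hidden_units),
            "head_cls": Dense(rng, cfg.hidden_units, 2),
            "head_reg": Dense(rng, cfg.hidden_units, 4),
        }

    def _state(self) -> dict[str, dict[str, np.ndarray]]:
        return {name: layer.state() for name, layer in self.layers.items()}

    def _load_state(self, state: dict[str, dict[str, np.ndarray]]) -> None:
        for name, layer in self.layers.items():
            if name not in state:
                raise ValueError(f"weights file missing layer {name!r}")
            if state[name]["W"].shape != layer.W.shape:
                raise ValueError(
                    f"incompatible weights for {name!r}: "
                    f"{state[name]['W'].shape} vs {layer.W.shape}; "
                    "weights and config do not belong together"
                )
            layer.load_state(state[name])

    # -- per-image preparation ----------------------------------------------

    def _prepare(self, image: ImageLike, anns: Sequence[Annotation]) -> _ImageTensors:
        cfg = self.config
        arr, scaled_anns, _ = preprocess(image, anns, cfg)
        feat = self._backbone(arr, cfg.feature_stride)
        patches = im2col3x3(feat)
        anchors = generate_anchors(
            feat.shape[0],
            feat.shape[1],
            cfg.feature_stride,
            cfg.anchor_scales,
            cfg.anchor_aspect_ratios,
        )
        gt = np.array(
            [a.box.as_tuple() for a in scaled_anns], dtype=float
        ).reshape(-1, 4)
        labels = -np.ones(anchors.shape[0], dtype=int)
        targets = np.zeros((anchors.shape[0], 4))
        if gt.shape[0]:
            ious = iou_matrix(anchors, gt)
            best_gt = ious.argmax(axis=1)
            best_iou = ious.max(axis=1)
            labels[best_iou < cfg.rpn_negative_iou] = 0
            labels[best_iou >= cfg.rpn_positive_iou] = 1
            # the best anchor for each gt is always positive, so every
            # ground truth owns at least one anchor
            per_gt_best = ious.max(axis=0)
            for g in range(gt.shape[0]):
                labels[np.isclose(ious[:, g], per_gt_best[g])] = 1
            pos = labels == 1
            targets[pos] = encode_deltas(gt[best_gt[pos]], anchors[pos])
        h, w = arr.shape[:2]
        return _ImageTensors(feat, patches, anchors, gt, labels, targets, (w, h))

    # -- forward passes ------------------------------------------------------

    def _rpn_forward(self, patches: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pre = self.layers["rpn_hidden"].forward(patches)
        hid = relu(pre)
        A = self.config.anchors_per_cell
        cls = self.layers["rpn_cls"].forward(hid).reshape(-1, 2)  # (P*A, 2)
        reg = self.layers["rpn_reg"].forward(hid).reshape(-1, 4)
        return pre, cls, reg

    def _proposals(
        self,
        anchors: np.ndarray,
        cls_logits: np.ndarray,
        reg: np.ndarray,
        size: tuple[int, int],
        count: int,
    ) -> np.ndarray:
        w, h = size
        scores = softmax(cls_logits)[:, 1]
        boxes = clip_boxes(decode_deltas(anchors, reg), w, h)
        wide = (boxes[:, 2] - boxes[:, 0] >= 4) & (boxes[:, 3] - boxes[:, 1] >= 4)
        idx = np.flatnonzero(wide)
        if idx.size == 0:
            return np.empty((0, 4))
        order = idx[np.argsort(-scores[idx], kind="stable")][:600]
        keep = nms(boxes[order], scores[order], self.config.proposal_nms_iou)
        return boxes[order[keep[:count]]]

    def _roi_pool(self, feat: np.ndarray, rois: np.ndarray) -> np.ndarray:
        """Max-pool each RoI (and a 50%-dilated context box) to a fixed
        P x P grid on the feature map; rois are in scaled-image pixels."""
        cfg = self.config
        s = cfg.feature_stride
        P = cfg.roi_pool_size
        hf, wf, c = feat.shape
        out = np.empty((rois.shape[0], 2 * c * P * P))
        for r, roi in enumerate(rois):
            vecs = []
            for dilate in (0.0, 0.5):
                bw = roi[2] - roi[0]
                bh = roi[3] - roi[1]
                x1 = max((roi[0] - dilate * bw) / s, 0.0)
                x2 = min((roi[2] + dilate * bw) / s, wf)
                y1 = max((roi[1] - dilate * bh) / s, 0.0)
                y2 = min((roi[3] + dilate * bh) / s, hf)
                xs = np.linspace(x1, x2, P + 1)
                ys = np.linspace(y1, y2, P + 1)
                grid = np.empty((P, P, c))
                for i in range(P):
                    r0 = int(np.floor(ys[i]))
                    r1 = max(int(np.ceil(ys[i + 1])), r0 + 1)
                    for j in range(P):
                        c0 = int(np.floor(xs[j]))
                        c1 = max(int(np.ceil(xs[j + 1])), c0 + 1)
                        grid[i, j] = feat[
                            min(r0, hf - 1) : min(r1, hf),
                            min(c0, wf - 1) : min(c1, wf),
                        ].max(axis=(0, 1))
                vecs.append(grid.ravel())
            out[r] = np.concatenate(vecs)
        return out

    # -- training ------------------------------------------------------------

    def fit(
        self,
        log_path: Optional[str | Path] = None,
        verbose: bool = False,
    ) -> "TrainingResults":
        """Run the training loop; returns results built on the last
        checkpoint's weights."""
        cfg = self.config
        tensors = [self._prepare(img, anns) for img, anns in self._dataset]
        if all(t.gt_boxes.shape[0] == 0 for t in tensors):
            raise ValueError("no annotations in the training set")

        history: list[LossRecord] = []
        totals: list[float] = []
        best_state = self._state()
        saved_epochs: list[int] = []
        for epoch in range(1, cfg.epochs + 1):
            order = self._rng.permutation(len(tensors))
            comps = np.zeros(4)
            accs: list[float] = []
            for t_idx in order:
                c1, c2, c3, c4, acc = self._train_one(tensors[t_idx])
                comps += (c1, c2, c3, c4)
                accs.append(acc)
            comps /= len(tensors)
            record = LossRecord.from_components(
                epoch, comps[0], comps[1], comps[2], comps[3], float(np.mean(accs))
            )
            history.append(record)
            prior = totals.copy()
            totals.append(record.total_loss)
            if not prior or record.total_loss < float(np.mean(prior)):
                best_state = self._state()
                saved_epochs.append(epoch)
            if verbose:
                logger.info(
                    "epoch %d: total_loss=%.4f rpn_acc=%.3f",
                    epoch,
                    record.total_loss,
                    record.rpn_classifier_accuracy,
                )
        self._load_state(best_state)
        results = TrainingResults(
            model=self,
            history=history,
            checkpoint_epoch_list=saved_epochs,
        )
        if log_path is not None:
            results.write_history(log_path)
        return results

    def _train_one(self, t: _ImageTensors) -> tuple[float, float, float, float, float]:
        cfg = self.config
        rng = self._rng
        A = cfg.anchors_per_cell

        # ---- RPN pass
        pre, cls_logits, reg = self._rpn_forward(t.patches)
        pos_idx = np.flatnonzero(t.anchor_labels == 1)
        neg_idx = np.flatnonzero(t.anchor_labels == 0)
        n_pos = min(pos_idx.size, cfg.rpn_batch_size // 2)
        n_neg = min(neg_idx.size, cfg.rpn_batch_size - n_pos)
        sample_pos = rng.choice(pos_idx, n_pos, replace=False) if n_pos else np.empty(0, int)
        sample_neg = rng.choice(neg_idx, n_neg, replace=False) if n_neg else np.empty(0, int)
        sample = np.concatenate([sample_pos, sample_neg]).astype(int)
        labels = t.anchor_labels[sample]
        l_cls, d_cls_s, acc = softmax_cross_entropy(cls_logits[sample], labels)
        l_reg, d_reg_p = smooth_l1(reg[sample_pos], t.anchor_targets[sample_pos])

        d_cls = np.zeros_like(cls_logits)
        d_cls[sample] = d_cls_s
        d_reg = np.zeros_like(reg)
        if sample_pos.size:
            d_reg[sample_pos] = d_reg_p
        dh = self.layers["rpn_cls"].backward(d_cls.reshape(-1, 2 * A))
        dh += self.layers["rpn_reg"].backward(d_reg.reshape(-1, 4 * A))
        self.layers["rpn_hidden"].backward(relu_grad(pre, dh))
        for name in ("rpn_hidden", "rpn_cls", "rpn_reg"):
            self.layers[name].step(cfg.learning_rate)

        # ---- detector head pass (proposals from the just-updated RPN,
        # ground truth appended so the heads always see true positives)
        _, cls_logits, reg = self._rpn_forward(t.patches)
        props = self._proposals(
            t.anchors, cls_logits, reg, t.size, cfg.proposal_count_train
        )
        rois = np.vstack([props, t.gt_boxes]) if props.size else t.gt_boxes
        ious = iou_matrix(rois, t.gt_boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious.max(axis=1)
        fg = np.flatnonzero(best_iou >= 0.5)
        bg = np.flatnonzero(best_iou < 0.5)
        n_fg = min(fg.size, cfg.minibatch_rois // 2)
        n_bg = min(bg.size, cfg.minibatch_rois - n_fg)
        sel_fg = rng.choice(fg, n_fg, replace=False) if n_fg else np.empty(0, int)
        sel_bg = rng.choice(bg, n_bg, replace=False) if n_bg else np.empty(0, int)
        sel = np.concatenate([sel_fg, sel_bg]).astype(int)
        roi_labels = (best_iou[sel] >= 0.5).astype(int)

        pooled = self._roi_pool(t.feat, rois[sel])
        pre_h = self.layers["head_fc"].forward(pooled)
        hid = relu(pre_h)
        h_cls = self.layers["head_cls"].forward(hid)
        h_reg = self.layers["head_reg"].forward(hid)

        l_dcls, d_hcls, _ = softmax_cross_entropy(h_cls, roi_labels)
        fg_rows = np.flatnonzero(roi_labels == 1)
        reg_targets = encode_deltas(
            t.gt_boxes[best_gt[sel[fg_rows]]], rois[sel[fg_rows]]
        ) if fg_rows.size else np.empty((0, 4))
        l_dreg, d_hreg_fg = smooth_l1(h_reg[fg_rows], reg_targets)
        d_hreg = np.zeros_like(h_reg)
        if fg_rows.size:
            d_hreg[fg_rows] = d_hreg_fg

        dh = self.layers["head_cls"].backward(d_hcls)
        dh += self.layers["head_reg"].backward(d_hreg)
        self.layers["head_fc"].backward(relu_grad(pre_h, dh))
        for name in ("head_fc", "head_cls", "head_reg"):
            self.layers[name].step(cfg.learning_rate)

        return l_cls, l_reg, l_dcls, l_dreg, acc

    # -- inference ------------------------------------------------------------

    def detect(
        self,
        image: ImageLike,
        score_threshold: Optional[float] = None,
        nms_iou: Optional[float] = None,
    ) -> list[Detection]:
        """Detect micro-domains on one image.

        Deterministic; boxes come back in original (pre-rescale) pixel
        coordinates, clipped to image bounds, after class-wise NMS.
        """
        cfg = self.config
        thr = cfg.score_threshold if score_threshold is None else score_threshold
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"score threshold must be in [0, 1], got {thr}")
        nms_thr = cfg.nms_iou if nms_iou is None else nms_iou
        orig = _load_image(image)
        oh, ow = orig.shape[:2]
        arr, _, scale = preprocess(orig, [], cfg)
        feat = self._backbone(arr, cfg.feature_stride)
        patches = im2col3x3(feat)
        anchors = generate_anchors(
            feat.shape[0],
            feat.shape[1],
            cfg.feature_stride,
            cfg.anchor_scales,
            cfg.anchor_aspect_ratios,
        )
        _, cls_logits, reg = self._rpn_forward(patches)
        h, w = arr.shape[:2]
        props = self._proposals(
            anchors, cls_logits, reg, (w, h), cfg.proposal_count_infer
        )
        if props.shape[0] == 0:
            return []
        pooled = self._roi_pool(feat, props)
        hid = relu(self.layers["head_fc"].forward(pooled))
        scores = softmax(self.layers["head_cls"].forward(hid))[:, 1]
        deltas = self.layers["head_reg"].forward(hid)
        boxes = clip_boxes(decode_deltas(props, deltas), w, h)
        ok = (scores >= thr) & (boxes[:, 2] - boxes[:, 0] >= 1) & (
            boxes[:, 3] - boxes[:, 1] >= 1
        )
        boxes, scores = boxes[ok], scores[ok]
        keep = nms(boxes, scores, nms_thr)
        boxes, scores = boxes[keep], scores[keep]
        detections: list[Detection] = []
        for box, score in zip(boxes / scale, scores):
            x1 = int(np.clip(np.floor(box[0] + 0.5), 0, ow - 1))
            y1 = int(np.clip(np.floor(box[1] + 0.5), 0, oh - 1))
            x2 = int(np.clip(np.floor(box[2] + 0.5), x1 + 1, ow))
            y2 = int(np.clip(np.floor(box[3] + 0.5), y1 + 1, oh))
            detections.append(
                Detection(PixelBox(x1, y1, x2, y2), float(score), self.category)
            )
        return detections


# ---------------------------------------------------------------------------
# results / artifacts
# ---------------------------------------------------------------------------

@dataclass
class ModelArtifact:
    """A saved model: weights + config + loss history, loadable together."""

    weights_path: Path
    config_path: Path
    history_path: Path

    def __post_init__(self) -> None:
        for p in (self.weights_path, self.config_path, self.history_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class TrainingResults:
    """Outcome of a training run: fitted model, loss history, checkpoints."""

    model: FragmentViewDetector
    history: list[LossRecord]
    checkpoint_epoch_list: list[int] = field(default_factory=list)

    @property
    def final_epoch(self) -> int:
        return self.checkpoint_epoch_list[-1] if self.checkpoint_epoch_list else 0

    def detect(self, image: ImageLike, **kwargs) -> list[Detection]:
        return self.model.detect(image, **kwargs)

    def summary(self) -> str:
        first, last = self.history[0], self.history[-1]
        lines = [
            "Fragment-view detector training",
            "-" * 42,
            f"{'epochs':<28}{len(self.history)}",
            f"{'training images':<28}{len(self.model._dataset)}",
            f"{'backbone':<28}{self.model.config.backbone}",
            f"{'checkpoints saved':<28}{len(self.checkpoint_epoch_list)}"
            f" (final: epoch {self.final_epoch})",
            f"{'total_loss first -> last':<28}"
            f"{first.total_loss:.4f} -> {last.total_loss:.4f}",
            f"{'rpn accuracy first -> last':<28}"
            f"{first.rpn_classifier_accuracy:.3f} -> "
            f"{last.rpn_classifier_accuracy:.3f}",
        ]
        return "\n".join(lines)

    def write_history(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(HISTORY_COLUMNS)
            for rec in self.history:
                writer.writerow([getattr(rec, c) for c in HISTORY_COLUMNS])

    def save(self, out_dir: str | Path) -> ModelArtifact:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        weights_path = out_dir / WEIGHTS_FILE
        flat = {}
        for name, layer in self.model.layers.items():
            st = layer.state()
            flat[f"{name}.W"] = st["W"]
            flat[f"{name}.b"] = st["b"]
        np.savez(weights_path, **flat)
        config_path = out_dir / CONFIG_FILE
        self.model.config.to_json(config_path)
        history_path = out_dir / HISTORY_FILE
        self.write_history(history_path)
        return ModelArtifact(weights_path, config_path, history_path)


def load_artifact(artifact: ModelArtifact | str | Path) -> TrainingResults:
    """Load a saved model; weights and config must round-trip together."""
    if not isinstance(artifact, ModelArtifact):
        d = Path(artifact)
        artifact = ModelArtifact(d / WEIGHTS_FILE, d / CONFIG_FILE, d / HISTORY_FILE)
    config = DetectorConfig.from_json(artifact.config_path)
    with np.load(artifact.weights_path) as npz:
        state: dict[str, dict[str, np.ndarray]] = {}
        for key in npz.files:
            name, part = key.rsplit(".", 1)
            state.setdefault(name, {})[part] = npz[key]
    # a model needs a dataset shell only for construction; detection
    # never touches it
    dummy = np.full((8, 8, 3), 255, dtype=np.uint8)
    model = FragmentViewDetector(
        [(dummy, [Annotation("", PixelBox(0, 0, 1, 1), "m")])], config
    )
    model._load_state(state)
    history: list[LossRecord] = []
    with open(artifact.history_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            history.append(
                LossRecord(
                    epoch=int(row["epoch"]),
                    **{c: float(row[c]) for c in HISTORY_COLUMNS[1:]},
                )
            )
    totals = [r.total_loss for r in history]
    return TrainingResults(model, history, checkpoint_epochs(totals))


# ---------------------------------------------------------------------------
# functional pipeline surface
# ---------------------------------------------------------------------------

def train(
    dataset: Sequence[tuple[ImageLike, Sequence[Annotation]]],
    config: Optional[DetectorConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> ModelArtifact | TrainingResults:
    """Train a detector; saves an artifact when ``out_dir`` is given."""
    results = FragmentViewDetector(dataset, config).fit()
    if out_dir is not None:
        return results.save(out_dir)
    return results


def detect(
    model: ModelArtifact | TrainingResults | str | Path,
    image: ImageLike,
    **overrides,
) -> list[Detection]:
    """Run inference with a trained model or a saved artifact."""
    if isinstance(model, TrainingResults):
        return model.detect(image, **overrides)
    return load_artifact(model).detect(image, **overrides)
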