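"""Detector configuration: every tunable of the training/inference loop."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path


@dataclass(frozen=True)
class DetectorConfig:
    """All knobs of the two-stage detector.

    The IoU thresholds and NMS defaults follow the original Faster R-CNN
    conventions (positive anchors at IoU 0.7, negatives below 0.3,
    detection NMS at 0.5, score threshold 0.7).  The backbone default is
    deliberately tiny so training runs on one CPU in minutes.
    """

    target_short_side_px: int = 240
    anchor_scales: tuple[int, ...] = (24, 48, 96)
    anchor_aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_positive_iou: float = 0.7
    rpn_negative_iou: float = 0.3
    minibatch_rois: int = 64
    epochs: int = 40
    score_threshold: float = 0.7
    nms_iou: float = 0.5
    seed: int = 0
    backbone: str = "tiny"
    # optimisation / proposal internals
    learning_rate: float = 0.005
    rpn_batch_size: int = 128
    proposal_count_train: int = 24
    proposal_count_infer: int = 40
    proposal_nms_iou: float = 0.7
    roi_pool_size: int = 4
    hidden_units: int = 64
    rpn_hidden_units: int = 32
    feature_stride: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.rpn_negative_iou < self.rpn_positive_iou <= 1.0):
            raise ValueError(
                "require 0 <= rpn_negative_iou < rpn_positive_iou <= 1, got "
                f"{self.rpn_negative_iou} / {self.rpn_positive_iou}"
            )
        for name in ("score_threshold", "nms_iou", "proposal_nms_iou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.target_short_side_px < 16:
            raise ValueError("target_short_side_px unreasonably small")
        if not self.anchor_scales or not self.anchor_aspect_ratios:
            raise ValueError("need at least one anchor scale and ratio")
        if self.minibatch_rois < 1 or self.rpn_batch_size < 1:
            raise ValueError("minibatch sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def anchors_per_cell(self) -> int:
        return len(self.anchor_scales) * len(self.anchor_aspect_ratios)

    def replace(self, **kwargs) -> "DetectorConfig":
        return replace(self, **kwargs)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectorConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["anchor_scales"] = tuple(d["anchor_scales"])
        d["anchor_aspect_ratios"] = tuple(d["anchor_aspect_ratios"])
        return cls(**d)
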