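"""Fixed feature backbones.

The "tiny" backbone is a deterministic, non-learned feature extractor:
the image is reduced to an ink-density map (fragment bars are dark or
saturated against a light background) and pooled into stride-sized cells
with a handful of channels per cell.  The learnable parts of the detector
(RPN convolution and the fully connected heads) sit on top of this map.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

FeatureFn = Callable[[np.ndarray, int], np.ndarray]

INK_THRESHOLD = 0.15


def ink_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel 'ink' in [0, 1]: how far the pixel is from white.

    Uses the minimum RGB channel so every saturated bar colour scores
    high and the white background scores 0.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.min(axis=2)
    return 1.0 - arr / 255.0


def _pool_cells(x: np.ndarray, stride: int) -> np.ndarray:
    """Reshape (H, W) into (H//s, W//s, s*s) cell blocks (zero-padded)."""
    h, w = x.shape
    ph = (stride - h % stride) % stride
    pw = (stride - w % stride) % stride
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)))
    hh, ww = x.shape[0] // stride, x.shape[1] // stride
    return (
        x.reshape(hh, stride, ww, stride)
        .transpose(0, 2, 1, 3)
        .reshape(hh, ww, stride * stride)
    )


def tiny_backbone(image: np.ndarray, stride: int) -> np.ndarray:
    """Five channels per cell: mean ink, max ink, occupancy, |dy|, |dx|."""
    ink = ink_map(image)
    gy = np.abs(np.diff(ink, axis=0, prepend=ink[:1]))
    gx = np.abs(np.diff(ink, axis=1, prepend=ink[:, :1]))
    cells = _pool_cells(ink, stride)
    feat = np.stack(
        [
            cells.mean(axis=2),
            cells.max(axis=2),
            (cells > INK_THRESHOLD).mean(axis=2),
            _pool_cells(gy, stride).mean(axis=2),
            _pool_cells(gx, stride).mean(axis=2),
        ],
        axis=2,
    )
    return feat


BACKBONES: dict[str, tuple[FeatureFn, int]] = {
    # name -> (function, number of channels)
    "tiny": (tiny_backbone, 5),
}


def get_backbone(name: str) -> tuple[FeatureFn, int]:
    if name not in BACKBONES:
        raise ValueError(
            f"unknown backbone {name!r}; available: {sorted(BACKBONES)}"
        )
    return BACKBONES[name]


def im2col3x3(feat: np.ndarray) -> np.ndarray:
    """3x3 neighbourhood patches of a (H, W, C) map, zero-padded.

    Returns shape (H*W, 9*C); this turns the RPN's 3x3 convolution into a
    single matrix product.
    """
    h, w, c = feat.shape
    padded = np.pad(feat, ((1, 1), (1, 1), (0, 0)))
    cols = np.empty((h, w, 9 * c))
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, :, k * c : (k + 1) * c] = padded[dy : dy + h, dx : dx + w]
            k += 1
    return cols.reshape(h * w, 9 * c)
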