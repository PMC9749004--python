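"""Deterministic fragment-view rendering.

A fragment view shows each single-molecule complex as one thin row of
filled bars: bars sit at their genomic x positions, complexes are stacked
along y grouped by cluster, so a micro-domain appears as a dense block of
aligned bars.  Alongside the PNG we record a :class:`RenderMap` — the exact
affine mapping between plot-area pixels and the genomic region — which is
what later turns detected pixel boxes back into genomic coordinates.

The x mapping is ``px(g) = plot_x0 + floor((g - start) / L * W)`` over the
half-open plot area, so adjacent genomic intervals tile into adjacent,
non-overlapping pixel runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .types import Annotation, Complex, GenomicInterval, PixelBox

# a colour-blind-safe cycle for cluster bands
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (23, 190, 207),
)
NOISE_COLOR = (150, 150, 150)


@dataclass(frozen=True)
class RenderStyle:
    """Geometry and colours of a fragment view.

    Margins are (left, right, top, bottom) in pixels; the plot area is the
    image minus margins.  Axis decorations never enter the plot area, so
    the pixel-to-genomic mapping stays affine over it.
    """

    image_width_px: int = 480
    image_height_px: int = 240
    margins: tuple[int, int, int, int] = (10, 10, 10, 20)
    row_height_px: int = 2
    inter_cluster_gap_px: int = 4
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.row_height_px <= 0 or self.inter_cluster_gap_px < 0:
            raise ValueError("row height must be positive, gap non-negative")
        if any(m < 0 for m in self.margins):
            raise ValueError("margins must be non-negative")
        left, right, top, bottom = self.margins
        if left + right >= self.image_width_px:
            raise ValueError("horizontal margins leave no plot area")
        if top + bottom >= self.image_height_px:
            raise ValueError("vertical margins leave no plot area")

    @property
    def plot_x0(self) -> int:
        return self.margins[0]

    @property
    def plot_x1(self) -> int:
        return self.image_width_px - self.margins[1]

    @property
    def plot_y0(self) -> int:
        return self.margins[2]

    @property
    def plot_y1(self) -> int:
        return self.image_height_px - self.margins[3]


@dataclass
class RenderMap:
    """Invertible bookkeeping between one image's plot area and its region."""

    region: GenomicInterval
    image_width_px: int
    image_height_px: int
    plot_x0: int
    plot_x1: int
    plot_y0: int
    plot_y1: int
    row_of_complex: list[str] = field(default_factory=list)
    cluster_bands: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.plot_x0 < self.plot_x1 <= self.image_width_px):
            raise ValueError("plot x bounds out of order")
        if not (0 <= self.plot_y0 < self.plot_y1 <= self.image_height_px):
            raise ValueError("plot y bounds out of order")
        bands = sorted(self.cluster_bands.values())
        for (a0, a1), (b0, b1) in zip(bands, bands[1:]):
            if b0 < a1:
                raise ValueError("cluster bands overlap")
        for y0, y1 in bands:
            if y0 < self.plot_y0 or y1 > self.plot_y1 or y1 <= y0:
                raise ValueError("cluster band outside plot area")

    @property
    def plot_width(self) -> int:
        return self.plot_x1 - self.plot_x0

    def px(self, g: int) -> int:
        """Map a genomic position to a plot-area x pixel (floor rule)."""
        L = self.region.length
        frac = (g - self.region.start) / L
        return self.plot_x0 + int(np.floor(frac * self.plot_width))

    def genomic(self, x: float) -> int:
        """Inverse of :meth:`px` (round half-up), clipped to the region."""
        frac = (x - self.plot_x0) / self.plot_width
        g = self.region.start + int(np.floor(frac * self.region.length + 0.5))
        return min(max(g, self.region.start), self.region.end)

    # -- sidecar serialization ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "region": {
                "chrom": self.region.chrom,
                "start": self.region.start,
                "end": self.region.end,
            },
            "image_width_px": self.image_width_px,
            "image_height_px": self.image_height_px,
            "plot_x0": self.plot_x0,
            "plot_x1": self.plot_x1,
            "plot_y0": self.plot_y0,
            "plot_y1": self.plot_y1,
            "row_of_complex": self.row_of_complex,
            "cluster_bands": [
                [c, y0, y1] for c, (y0, y1) in sorted(self.cluster_bands.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RenderMap":
        return cls(
            region=GenomicInterval(**d["region"]),
            image_width_px=d["image_width_px"],
            image_height_px=d["image_height_px"],
            plot_x0=d["plot_x0"],
            plot_x1=d["plot_x1"],
            plot_y0=d["plot_y0"],
            plot_y1=d["plot_y1"],
            row_of_complex=list(d.get("row_of_complex", [])),
            cluster_bands={c: (y0, y1) for c, y0, y1 in d.get("cluster_bands", [])},
        )


def sidecar_path(image_path: str | Path) -> Path:
    return Path(str(image_path) + ".map.json")


def write_render_map(rmap: RenderMap, image_path: str | Path) -> Path:
    path = sidecar_path(image_path)
    with open(path, "w") as fh:
        json.dump(rmap.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_render_map(image_path: str | Path) -> RenderMap:
    path = Path(str(image_path))
    if path.suffix != ".json":
        path = sidecar_path(path)
    with open(path) as fh:
        return RenderMap.from_dict(json.load(fh))


def _order_complexes(complexes: Sequence[Complex]) -> list[Complex]:
    """Deterministic stacking order: (cluster, leftmost start, id).

    Unlabelled complexes form their own residual group drawn last.
    """
    max_label = max(
        (c.cluster for c in complexes if c.cluster is not None), default=-1
    )
    none_key = max_label + 1
    return sorted(
        complexes,
        key=lambda c: (
            c.cluster if c.cluster is not None else none_key,
            c.fragments[0].interval.start,
            c.id,
        ),
    )


def render_fragment_view(
    complexes: Sequence[Complex],
    region: GenomicInterval,
    style: Optional[RenderStyle] = None,
) -> tuple[Image.Image, RenderMap]:
    """Render complexes as a clustered fragment view.

    Complexes are drawn one row each, top to bottom, grouped by cluster
    with a vertical gap between clusters.  Output is byte-identical across
    runs for identical inputs.
    """
    style = style or RenderStyle()
    if region.length <= 0:
        raise ValueError("region has zero length")
    for cx in complexes:
        if not any(f.interval.overlaps(region) for f in cx.fragments):
            raise ValueError(f"complex {cx.id!r} does not overlap {region}")

    ordered = _order_complexes(complexes)
    max_label = max(
        (c.cluster for c in ordered if c.cluster is not None), default=-1
    )
    none_key = max_label + 1
    labels = [c.cluster if c.cluster is not None else none_key for c in ordered]
    distinct = sorted(set(labels))

    needed = len(ordered) * style.row_height_px + (
        max(len(distinct) - 1, 0)
    ) * style.inter_cluster_gap_px
    avail = style.plot_y1 - style.plot_y0
    if needed > avail:
        raise ValueError(
            f"{len(ordered)} complexes need {needed}px of plot height but only "
            f"{avail}px available; use a taller image or subsample complexes"
        )

    rmap = RenderMap(
        region=region,
        image_width_px=style.image_width_px,
        image_height_px=style.image_height_px,
        plot_x0=style.plot_x0,
        plot_x1=style.plot_x1,
        plot_y0=style.plot_y0,
        plot_y1=style.plot_y1,
    )

    img = Image.new(
        "RGB", (style.image_width_px, style.image_height_px), style.background
    )
    draw = ImageDraw.Draw(img)

    # axis baseline + ticks in the bottom margin (outside the plot area)
    if style.margins[3] >= 3:
        y_axis = style.plot_y1 + 1
        draw.line(
            [(style.plot_x0, y_axis), (style.plot_x1 - 1, y_axis)],
            fill=(0, 0, 0),
        )
        for k in range(5):
            x = style.plot_x0 + int(
                round(k / 4 * (style.plot_x1 - 1 - style.plot_x0))
            )
            draw.line([(x, y_axis), (x, y_axis + 2)], fill=(0, 0, 0))

    y = style.plot_y0
    current_label: Optional[int] = None
    band_start = y
    for cx, label in zip(ordered, labels):
        if current_label is not None and label != current_label:
            rmap.cluster_bands[current_label] = (band_start, y)
            y += style.inter_cluster_gap_px
            band_start = y
        current_label = label
        color = (
            NOISE_COLOR
            if cx.cluster is None
            else style.palette[label % len(style.palette)]
        )
        for frag in cx.fragments:
            iv = frag.interval.intersection(region)
            if iv is None:
                continue
            x1 = rmap.px(iv.start)
            x2 = max(rmap.px(iv.end), x1 + 1)  # never thinner than 1 px
            x2 = min(x2, style.plot_x1)
            x1 = min(x1, style.plot_x1 - 1)
            # PIL rectangle is inclusive on both corners
            draw.rectangle(
                [x1, y, x2 - 1, y + style.row_height_px - 1], fill=color
            )
        rmap.row_of_complex.append(cx.id)
        y += style.row_height_px
    if current_label is not None:
        rmap.cluster_bands[current_label] = (band_start, y)

    return img, rmap


def truth_boxes(
    rmap: RenderMap,
    truths: Sequence[tuple[GenomicInterval, int]],
    image_path: str = "",
) -> list[Annotation]:
    """Ground-truth boxes for planted intervals — the automated stand-in
    for drawing rectangles by hand in an annotation GUI.

    Each truth interval maps to x = [px(start), px(end)) and the full pixel
    band of its cluster.
    """
    annotations: list[Annotation] = []
    for interval, cluster in truths:
        if not rmap.region.contains(interval):
            raise ValueError(f"truth interval {interval} outside {rmap.region}")
        if cluster not in rmap.cluster_bands:
            raise ValueError(f"unknown cluster id {cluster}")
        x1 = rmap.px(interval.start)
        x2 = max(rmap.px(interval.end), x1 + 1)
        y1, y2 = rmap.cluster_bands[cluster]
        annotations.append(
            Annotation(image_path, PixelBox(x1, y1, x2, y2), "m")
        )
    return annotations
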