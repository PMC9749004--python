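"""Core domain types shared across the package.

Conventions used everywhere:

* Genomic intervals are 0-based, half-open ``[start, end)`` — the BED
  convention — so no coordinate shifting is ever needed on output.
* Pixel boxes are half-open ``[x1, x2) x [y1, y2)`` with the origin at the
  top-left corner, x rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Fragment:
    """One genomic fragment of a single-molecule chromatin complex."""

    interval: GenomicInterval
    complex_id: str


@dataclass
class Complex:
    """A single-molecule multi-way contact (one barcode group / GEM).

    ``cluster`` carries an externally supplied micro-domain cluster label
    (clustering itself is out of scope here); ``None`` means unclustered.
    """

    id: str
    fragments: list[Fragment] = field(default_factory=list)
    cluster: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"complex {self.id!r} has no fragments")
        chroms = {f.interval.chrom for f in self.fragments}
        if len(chroms) > 1:
            raise ValueError(
                f"complex {self.id!r} spans multiple chromosomes: {sorted(chroms)}"
            )
        self.fragments = sorted(self.fragments, key=lambda f: f.interval.start)

    @property
    def chrom(self) -> str:
        return self.fragments[0].interval.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.fragments[0].interval.start,
            max(f.interval.end for f in self.fragments),
        )


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned rectangle in image pixels, half-open on both axes."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self) -> None:
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError(
                f"degenerate box ({self.x1},{self.y1},{self.x2},{self.y2})"
            )

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class Annotation:
    """One ground-truth rectangle on one image ("m" = micro-domain)."""

    image_path: str
    box: PixelBox
    category: str = "m"


@dataclass(frozen=True)
class Detection:
    """A detector output: box in original image pixels plus a class score."""

    box: PixelBox
    score: float
    category: str = "m"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class MicroDomainCall:
    """A called micro-domain: genomic interval + score + provenance boxes."""

    interval: GenomicInterval
    score: float
    source_boxes: tuple[PixelBox, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


def sort_detections(dets: Sequence[Detection]) -> list[Detection]:
    """Deterministic ordering: descending score, ties by leftmost box."""
    return sorted(dets, key=lambda d: (-d.score, d.box.x1, d.box.y1))
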