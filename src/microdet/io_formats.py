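"""Readers and writers for the package's on-disk formats.

Formats handled here:

* complex tables — tab-delimited, one fragment per row:
  ``complex_id  chrom  start  end  [cluster]`` (header optional).  This is
  the dialect a per-region extract of ChIA-Drop/SPRITE GEM data projects
  into: group the raw archive by barcode, keep one row per fragment.
* LabelMe-dialect JSON rectangle annotations (read only).
* the unified annotation table — one CSV row per ground-truth box:
  ``image_path,x1,y1,x2,y2,category``.
* BED6 output of micro-domain calls.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import (
    Annotation,
    Complex,
    Fragment,
    GenomicInterval,
    MicroDomainCall,
    PixelBox,
)

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = frozenset({"m"})


class ParseError(ValueError):
    """A malformed row in a tabular input, reported with its line number."""


class FormatError(ValueError):
    """A structurally invalid document (missing fields, bad values)."""


# ---------------------------------------------------------------------------
# complex tables
# ---------------------------------------------------------------------------

def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_complexes(
    path: str | Path,
    region: Optional[GenomicInterval] = None,
) -> list[Complex]:
    """Read a fragment table and group rows into complexes.

    A header line is auto-detected by a non-integer ``start`` field.  If
    ``region`` is given, only complexes with at least one fragment
    overlapping it are returned, and fragments are clipped to the region
    (fragments entirely outside are dropped from kept complexes).
    """
    path = Path(path)
    rows: dict[str, list[tuple[GenomicInterval, Optional[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise ParseError(
                    f"{path}:{lineno}: expected 4 or 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and not _is_int(fields[2]):
                continue  # header
            cid, chrom = fields[0], fields[1]
            if not _is_int(fields[2]) or not _is_int(fields[3]):
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"({fields[2]!r}, {fields[3]!r})"
                )
            start, end = int(fields[2]), int(fields[3])
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            cluster: Optional[int] = None
            if len(fields) == 5 and fields[4] != "":
                if not _is_int(fields[4]):
                    raise ParseError(
                        f"{path}:{lineno}: non-integer cluster {fields[4]!r}"
                    )
                cluster = int(fields[4])
            if cid not in rows:
                order.append(cid)
                rows[cid] = []
            rows[cid].append((GenomicInterval(chrom, start, end), cluster))

    complexes: list[Complex] = []
    for cid in order:
        entries = rows[cid]
        clusters = {c for _, c in entries if c is not None}
        if len(clusters) > 1:
            raise ParseError(
                f"{path}: complex {cid!r} has conflicting cluster labels"
            )
        cluster = clusters.pop() if clusters else None
        intervals = [iv for iv, _ in entries]
        if region is not None:
            kept = []
            for iv in intervals:
                clipped = iv.intersection(region)
                if clipped is not None:
                    kept.append(clipped)
            if not kept:
                continue
            intervals = kept
        frags = [Fragment(iv, cid) for iv in intervals]
        try:
            complexes.append(Complex(cid, frags, cluster))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return complexes


def write_complexes(complexes: Iterable[Complex], path: str | Path) -> None:
    """Write complexes back to the tab-delimited fragment table."""
    with open(path, "w") as fh:
        fh.write("complex_id\tchrom\tstart\tend\tcluster\n")
        for cx in complexes:
            cl = "" if cx.cluster is None else str(cx.cluster)
            for frag in cx.fragments:
                iv = frag.interval
                fh.write(f"{cx.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{cl}\n")


# ---------------------------------------------------------------------------
# LabelMe rectangles
# ---------------------------------------------------------------------------

def import_labelme(json_path: str | Path) -> list[Annotation]:
    """Import rectangle shapes from a LabelMe-dialect JSON document.

    Corner order is normalized so x1 < x2 and y1 < y2.  Non-rectangle
    shapes are skipped with a warning; a zero-area rectangle is an error.
    """
    json_path = Path(json_path)
    with open(json_path) as fh:
        doc = json.load(fh)
    for key in ("imageWidth", "imageHeight"):
        if key not in doc:
            raise FormatError(f"{json_path}: missing required field {key!r}")
    image_path = doc.get("imagePath", "")
    annotations: list[Annotation] = []
    for shape in doc.get("shapes", []):
        stype = shape.get("shape_type", "rectangle")
        if stype != "rectangle":
            logger.warning(
                "%s: skipping non-rectangle shape of type %r", json_path, stype
            )
            continue
        points = shape.get("points", [])
        if len(points) != 2:
            raise FormatError(
                f"{json_path}: rectangle must have exactly 2 corner points"
            )
        (xa, ya), (xb, yb) = points
        x1, x2 = sorted((int(round(xa)), int(round(xb))))
        y1, y2 = sorted((int(round(ya)), int(round(yb))))
        if x1 == x2 or y1 == y2:
            raise FormatError(f"{json_path}: degenerate (zero-area) rectangle")
        annotations.append(
            Annotation(image_path, PixelBox(x1, y1, x2, y2), shape.get("label", "m"))
        )
    return annotations


# ---------------------------------------------------------------------------
# unified annotation table
# ---------------------------------------------------------------------------

def write_annotation_table(
    annotations: Sequence[Annotation], path: str | Path
) -> None:
    """Write the unified annotation document: one CSV row per box."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for ann in annotations:
            writer.writerow(
                [ann.image_path, *ann.box.as_tuple(), ann.category]
            )


def read_annotation_table(
    path: str | Path,
    categories: frozenset[str] | set[str] = DEFAULT_CATEGORIES,
) -> list[Annotation]:
    """Read the unified annotation document written by
    :func:`write_annotation_table`."""
    path = Path(path)
    annotations: list[Annotation] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields")
            image_path, x1, y1, x2, y2, category = row
            if category not in categories:
                raise FormatError(
                    f"{path}:{lineno}: unknown category {category!r} "
                    f"(declared: {sorted(categories)})"
                )
            try:
                box = PixelBox(int(x1), int(y1), int(x2), int(y2))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            annotations.append(Annotation(image_path, box, category))
    return annotations


# ---------------------------------------------------------------------------
# BED6 output
# ---------------------------------------------------------------------------

def write_bed(calls: Sequence[MicroDomainCall], path: str | Path) -> None:
    """Write micro-domain calls as BED6 (score scaled to 0-1000)."""
    with open(path, "w") as fh:
        for k, call in enumerate(calls, start=1):
            iv = call.interval
            score = int(round(call.score * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tm_{k}\t{score}\t.\n")


def read_bed(path: str | Path) -> list[MicroDomainCall]:
    """Read BED back into calls (inverse of :func:`write_bed`)."""
    calls: list[MicroDomainCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            score = int(fields[4]) / 1000.0 if len(fields) >= 5 else 0.0
            calls.append(MicroDomainCall(iv, min(max(score, 0.0), 1.0)))
    return calls
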