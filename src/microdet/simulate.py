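"""Synthetic clustered-complex generator with planted micro-domains.

Emulates a per-region extract of single-molecule multi-way contact data
(ChIA-Drop/SPRITE style): a handful of disjoint micro-domain intervals is
planted in the region; each domain receives a cluster of complexes whose
fragments fall entirely inside it; a fraction of background complexes have
fragments scattered over the whole region.  Every draw is uniform and
fully reproducible from the seed, and the planted intervals are returned
as ground truth, so rendering, training, detection and evaluation can all
run without any external download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import write_annotation_table, write_complexes
from .render import RenderMap, RenderStyle, render_fragment_view, truth_boxes, write_render_map
from .types import Annotation, Complex, Fragment, GenomicInterval

# default region: a ~200 kb Drosophila chr2R window, a realistic RAID scale
DEFAULT_REGION = GenomicInterval("chr2R", 3_220_194, 3_419_924)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated region.

    Defaults describe a mid-size domain-decomposition scenario: a ~200 kb
    region holding a few 15-40 kb micro-domains, ~25 complexes per domain
    with 3-8 fragments of 0.5-3 kb each, plus 10% background complexes.
    """

    region: GenomicInterval = DEFAULT_REGION
    n_domains: int = 3
    domain_length_range: tuple[int, int] = (15_000, 40_000)
    min_domain_gap: int = 8_000
    complexes_per_domain: int = 25
    fragments_per_complex_range: tuple[int, int] = (3, 8)
    fragment_length_range: tuple[int, int] = (500, 3_000)
    noise_complex_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("need at least one domain")
        for lo, hi in (
            self.domain_length_range,
            self.fragments_per_complex_range,
            self.fragment_length_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if self.min_domain_gap < 0:
            raise ValueError("min_domain_gap must be non-negative")
        if not 0.0 <= self.noise_complex_fraction < 1.0:
            raise ValueError("noise_complex_fraction must be in [0, 1)")
        if self.complexes_per_domain < 1:
            raise ValueError("complexes_per_domain must be positive")
        worst = (
            self.n_domains * self.domain_length_range[1]
            + (self.n_domains - 1) * self.min_domain_gap
        )
        if worst > self.region.length:
            raise ValueError(
                f"{self.n_domains} domains of up to "
                f"{self.domain_length_range[1]} bp with {self.min_domain_gap} bp "
                f"gaps cannot fit in {self.region.length} bp"
            )


def _place_domains(
    rng: np.random.Generator, spec: SyntheticSpec
) -> list[GenomicInterval]:
    """Place disjoint domain intervals uniformly, honouring the minimum gap.

    Constructive stars-and-bars placement: draw the lengths, then split the
    leftover slack into random extra gaps, so any feasible configuration can
    be produced and no rejection loop is needed.
    """
    n = spec.n_domains
    lo, hi = spec.domain_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    slack = spec.region.length - int(lengths.sum()) - (n - 1) * spec.min_domain_gap
    if slack < 0:
        raise ValueError("domains do not fit in region")  # pragma: no cover
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    extra = np.diff(np.concatenate(([cuts[0]], cuts)))
    extra[0] = cuts[0]
    intervals: list[GenomicInterval] = []
    pos = spec.region.start
    for i in range(n):
        pos += int(extra[i])
        start = pos
        end = start + int(lengths[i])
        intervals.append(GenomicInterval(spec.region.chrom, start, end))
        pos = end + spec.min_domain_gap
    return intervals


def _random_complex(
    rng: np.random.Generator,
    cid: str,
    window: GenomicInterval,
    spec: SyntheticSpec,
    cluster: int,
) -> Complex:
    """One complex with all fragments uniform inside ``window``."""
    nf_lo, nf_hi = spec.fragments_per_complex_range
    nf = int(rng.integers(nf_lo, nf_hi + 1))
    fl_lo, fl_hi = spec.fragment_length_range
    frags = []
    for _ in range(nf):
        length = int(rng.integers(fl_lo, min(fl_hi, window.length - 1) + 1))
        start = int(rng.integers(window.start, window.end - length + 1))
        frags.append(
            Fragment(GenomicInterval(window.chrom, start, start + length), cid)
        )
    return Complex(cid, frags, cluster)


def simulate(
    spec: SyntheticSpec,
) -> tuple[list[Complex], list[tuple[GenomicInterval, int]]]:
    """Simulate one region: complexes plus planted ground truth.

    Returns ``(complexes, truths)`` where each truth is
    ``(domain interval, cluster label)``; cluster label equals the domain
    index, and background complexes carry label ``n_domains``.
    The noise count is ``round(f * n_signal / (1 - f))`` so that noise
    complexes make up fraction ``f`` of the total.
    """
    rng = np.random.default_rng(spec.seed)
    domains = _place_domains(rng, spec)
    complexes: list[Complex] = []
    truths: list[tuple[GenomicInterval, int]] = []
    for d, domain in enumerate(domains):
        truths.append((domain, d))
        for j in range(spec.complexes_per_domain):
            complexes.append(
                _random_complex(rng, f"d{d}_c{j}", domain, spec, d)
            )
    n_signal = len(complexes)
    f = spec.noise_complex_fraction
    n_noise = int(round(f * n_signal / (1.0 - f)))
    for j in range(n_noise):
        complexes.append(
            _random_complex(rng, f"bg_{j}", spec.region, spec, spec.n_domains)
        )
    return complexes, truths


@dataclass
class Corpus:
    """Paths of a generated image corpus."""

    out_dir: Path
    image_paths: list[Path]
    annotation_table: Path
    truth_table: Path
    complex_tables: list[Path] = field(default_factory=list)

    def render_map(self, image_path: str | Path) -> RenderMap:
        from .render import read_render_map

        return read_render_map(image_path)


def make_dataset(
    spec_template: SyntheticSpec,
    n_images: int,
    style: Optional[RenderStyle] = None,
    out_dir: str | Path = ".",
    n_domains_per_image: Optional[Sequence[int]] = None,
) -> Corpus:
    """Generate a corpus: PNGs, map sidecars, one combined annotation CSV
    and a truth table.

    Image ``i`` uses seed ``spec_template.seed + i``, so the corpus is
    byte-identical when regenerated with the same base seed.
    ``n_domains_per_image`` optionally overrides the template's domain
    count per image (cycled), to mix images of different complexity.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    style = style or RenderStyle()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    image_paths: list[Path] = []
    complex_tables: list[Path] = []
    annotations: list[Annotation] = []
    truth_rows: list[tuple[str, str, int, int, int]] = []
    for i in range(n_images):
        spec_i = replace(spec_template, seed=spec_template.seed + i)
        if n_domains_per_image is not None:
            spec_i = replace(
                spec_i, n_domains=n_domains_per_image[i % len(n_domains_per_image)]
            )
        complexes, truths = simulate(spec_i)
        image, rmap = render_fragment_view(complexes, spec_i.region, style)
        image_path = out_dir / f"img_{i:03d}.png"
        image.save(image_path)
        write_render_map(rmap, image_path)
        table_path = out_dir / f"img_{i:03d}.complexes.tsv"
        write_complexes(complexes, table_path)
        annotations.extend(truth_boxes(rmap, truths, image_path.name))
        for interval, cluster in truths:
            truth_rows.append(
                (image_path.name, interval.chrom, interval.start, interval.end, cluster)
            )
        image_paths.append(image_path)
        complex_tables.append(table_path)

    annotation_table = out_dir / "annotations.csv"
    write_annotation_table(annotations, annotation_table)
    truth_table = out_dir / "truths.tsv"
    with open(truth_table, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["image_path", "chrom", "start", "end", "cluster"])
        writer.writerows(truth_rows)
    return Corpus(out_dir, image_paths, annotation_table, truth_table, complex_tables)


def read_truth_table(
    path: str | Path,
) -> dict[str, list[tuple[GenomicInterval, int]]]:
    """Read the truth table back, grouped by image path."""
    out: dict[str, list[tuple[GenomicInterval, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            image_path, chrom, start, end, cluster = row[:5]
            out.setdefault(image_path, []).append(
                (GenomicInterval(chrom, int(start), int(end)), int(cluster))
            )
    return out
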