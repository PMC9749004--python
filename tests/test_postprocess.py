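"""vIoU, merging, and the pixel-to-genomic transform."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdet.postprocess import (
    box_to_genomic,
    calls_from_detections,
    merge_detections,
    viou,
)
from microdet.render import RenderMap, render_fragment_view, truth_boxes
from microdet.types import Complex, Detection, Fragment, GenomicInterval, PixelBox


def _box(x1, y1, x2, y2):
    return PixelBox(x1, y1, x2, y2)


def _det(x1, y1, x2, y2, score=0.9):
    return Detection(_box(x1, y1, x2, y2), score)


def _viou_oracle(a: PixelBox, b: PixelBox) -> float:
    """Brute-force count of integer pixel rows in intersection / union."""
    ra = set(range(a.y1, a.y2))
    rb = set(range(b.y1, b.y2))
    union = ra | rb
    return len(ra & rb) / len(union) if union else 0.0


class TestViou:
    def test_identical_boxes(self):
        assert viou(_box(0, 0, 10, 10), _box(0, 0, 10, 10)) == 1.0

    def test_disjoint_y_ranges(self):
        assert viou(_box(0, 0, 10, 10), _box(0, 20, 10, 30)) == 0.0

    def test_partial_overlap_third(self):
        # y-ranges [0,10) and [5,15): 5 shared rows of 15 total
        assert viou(_box(0, 0, 10, 10), _box(0, 5, 10, 15)) == pytest.approx(1 / 3)
        assert _viou_oracle(_box(0, 0, 10, 10), _box(0, 5, 10, 15)) == pytest.approx(
            1 / 3
        )

    @given(
        y=st.tuples(*[st.integers(0, 50)] * 4),
        h=st.tuples(st.integers(1, 30), st.integers(1, 30)),
    )
    @settings(deadline=None, derandomize=True)
    def test_matches_row_counting_oracle(self, y, h):
        a = _box(0, y[0], 10, y[0] + h[0])
        b = _box(5, y[1], 15, y[1] + h[1])
        assert viou(a, b) == pytest.approx(_viou_oracle(a, b))
        assert viou(a, b) == pytest.approx(viou(b, a))
        assert 0.0 <= viou(a, b) <= 1.0
        if viou(a, b) == 1.0:
            assert (a.y1, a.y2) == (b.y1, b.y2)


def _merge_oracle(dets, thr=0.8):
    """Independent fixed-point merge oracle: each round links current
    boxes (vIoU > thr and x overlap), collapses whole components via DFS
    to their bounding boxes, and repeats until the set is stable."""
    items = [(d.box, d.score) for d in dets]
    while True:
        n = len(items)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                ba, bb = items[i][0], items[j][0]
                if viou(ba, bb) > thr and ba.x1 < bb.x2 and bb.x1 < ba.x2:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], []
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                comp.append(k)
                stack.extend(adj[k])
            comps.append(comp)
        if len(comps) == n:
            return sorted((*b.as_tuple(), s) for b, s in items)
        items = [
            (
                PixelBox(
                    min(items[k][0].x1 for k in comp),
                    min(items[k][0].y1 for k in comp),
                    max(items[k][0].x2 for k in comp),
                    max(items[k][0].y2 for k in comp),
                ),
                max(items[k][1] for k in comp),
            )
            for comp in comps
        ]


class TestMergeDetections:
    def test_single_detection_unchanged(self):
        d = _det(10, 10, 50, 60)
        assert merge_detections([d]) == [d]

    def test_same_band_overlapping_x_merged(self):
        a = _det(10, 10, 50, 60, 0.8)
        b = _det(40, 10, 90, 60, 0.95)
        (m,) = merge_detections([a, b])
        assert m.box == _box(10, 10, 90, 60)
        assert m.score == 0.95

    def test_disjoint_bands_retained(self):
        a = _det(10, 0, 50, 10)
        b = _det(10, 50, 50, 60)
        assert len(merge_detections([a, b])) == 2

    def test_same_band_disjoint_x_not_merged(self):
        # two distinct domains sharing one cluster band must not fuse
        a = _det(10, 10, 50, 60)
        b = _det(80, 10, 120, 60)
        assert len(merge_detections([a, b])) == 2

    def test_mixed_categories_rejected(self):
        a = Detection(_box(0, 0, 5, 5), 0.9, "m")
        b = Detection(_box(0, 0, 5, 5), 0.9, "x")
        with pytest.raises(ValueError, match="categories"):
            merge_detections([a, b])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = []
        for _ in range(rng.integers(2, 12)):
            x1 = int(rng.integers(0, 80))
            y1 = int(rng.integers(0, 40))
            dets.append(
                _det(
                    x1,
                    y1,
                    x1 + int(rng.integers(5, 40)),
                    y1 + int(rng.integers(5, 20)),
                    float(rng.uniform(0.1, 1.0)),
                )
            )
        got = sorted(
            (*d.box.as_tuple(), d.score) for d in merge_detections(dets)
        )
        assert got == pytest.approx(_merge_oracle(dets))

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_contractive(self, seed):
        rng = np.random.default_rng(seed + 100)
        dets = [
            _det(
                int(x1), int(y1), int(x1) + int(w), int(y1) + int(h), float(s)
            )
            for x1, y1, w, h, s in zip(
                rng.integers(0, 60, 8),
                rng.integers(0, 30, 8),
                rng.integers(5, 30, 8),
                rng.integers(5, 15, 8),
                rng.uniform(0.1, 1, 8),
            )
        ]
        once = merge_detections(dets)
        assert merge_detections(once) == once
        assert len(once) <= len(dets)
        for d in dets:
            assert any(
                m.box.x1 <= d.box.x1 and m.box.y1 <= d.box.y1
                and m.box.x2 >= d.box.x2 and m.box.y2 >= d.box.y2
                for m in once
            )


def _bare_map(plot_w=500, region_len=1000):
    return RenderMap(
        region=GenomicInterval("chrX", 0, region_len),
        image_width_px=plot_w,
        image_height_px=40,
        plot_x0=0,
        plot_x1=plot_w,
        plot_y0=0,
        plot_y1=36,
        cluster_bands={0: (0, 36)},
    )


class TestBoxToGenomic:
    def test_full_plot_width_maps_to_full_region(self):
        rmap = _bare_map()
        assert box_to_genomic(_box(0, 0, 500, 10), rmap) == GenomicInterval(
            "chrX", 0, 1000
        )

    def test_inverse_of_render_example(self):
        rmap = _bare_map()
        assert box_to_genomic(_box(125, 0, 250, 10), rmap) == GenomicInterval(
            "chrX", 250, 500
        )

    def test_overhang_clipped_to_region_end(self):
        rmap = _bare_map()
        iv = box_to_genomic(_box(400, 0, 600, 10), rmap)
        assert iv.end == 1000
        assert iv.start == 800

    def test_entirely_outside_plot_raises(self):
        rmap = RenderMap(
            region=GenomicInterval("chrX", 0, 1000),
            image_width_px=520,
            image_height_px=40,
            plot_x0=10,
            plot_x1=510,
            plot_y0=0,
            plot_y1=36,
        )
        with pytest.raises(ValueError, match="outside plot"):
            box_to_genomic(_box(0, 0, 10, 10), rmap)


class TestCallsFromDetections:
    def test_empty_detections_empty_calls(self):
        assert calls_from_detections([], _bare_map()) == []

    def test_truth_boxes_round_trip_within_one_pixel(self, single_region):
        spec, complexes, truths, image, rmap = single_region
        anns = truth_boxes(rmap, truths)
        dets = [Detection(a.box, 0.99) for a in anns]
        calls = calls_from_detections(dets, rmap)
        tol = int(np.ceil(spec.region.length / rmap.plot_width))
        assert len(calls) == len(truths)
        for call, (truth, _) in zip(calls, sorted(truths)):
            assert abs(call.interval.start - truth.start) <= tol
            assert abs(call.interval.end - truth.end) <= tol

    def test_duplicates_collapse_to_one_call(self):
        rmap = _bare_map()
        a = _det(100, 0, 200, 30, 0.9)
        b = _det(110, 2, 210, 30, 0.8)  # vIoU 28/30 > 0.8
        calls = calls_from_detections([a, b], rmap)
        assert len(calls) == 1
        assert calls[0].score == 0.9
        assert set(calls[0].source_boxes) == {a.box, b.box}
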