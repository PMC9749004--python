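"""Evaluation statistics against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from microdet.metrics import (
    evaluate_calls,
    giou,
    kfold_split,
    match_detections,
    pixel_iou,
    pr_curve_and_map,
    roc_and_auroc,
)
from microdet.types import Detection, GenomicInterval, MicroDomainCall, PixelBox


def _box(x1, y1, x2, y2):
    return PixelBox(x1, y1, x2, y2)


def _det(box, score):
    return Detection(box, score)


def _pixel_iou_oracle(a, b):
    """Brute-force discrete pixel counting."""
    pa = {(x, y) for x in range(a.x1, a.x2) for y in range(a.y1, a.y2)}
    pb = {(x, y) for x in range(b.x1, b.x2) for y in range(b.y1, b.y2)}
    return len(pa & pb) / len(pa | pb)


def _giou_oracle(a, b):
    """Brute-force base counting."""
    if a.chrom != b.chrom:
        return 0.0
    ba = set(range(a.start, a.end))
    bb = set(range(b.start, b.end))
    return len(ba & bb) / len(ba | bb)


class TestIoUVariants:
    def test_pixel_iou_identical(self):
        assert pixel_iou(_box(0, 0, 10, 10), _box(0, 0, 10, 10)) == 1.0

    def test_pixel_iou_disjoint(self):
        assert pixel_iou(_box(0, 0, 10, 10), _box(20, 0, 30, 10)) == 0.0

    def test_pixel_iou_half_shift(self):
        assert pixel_iou(_box(0, 0, 10, 10), _box(5, 0, 15, 10)) == pytest.approx(
            1 / 3
        )
        assert _pixel_iou_oracle(
            _box(0, 0, 10, 10), _box(5, 0, 15, 10)
        ) == pytest.approx(1 / 3)

    def test_giou_examples(self):
        a = GenomicInterval("chr2R", 100, 200)
        assert giou(a, a) == 1.0
        assert giou(a, GenomicInterval("chr2R", 150, 250)) == pytest.approx(1 / 3)
        assert giou(a, GenomicInterval("chr3L", 100, 200)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixtures_match_counting_oracles(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = _box(*_rand_box(rng))
            b = _box(*_rand_box(rng))
            assert pixel_iou(a, b) == pytest.approx(_pixel_iou_oracle(a, b))
            ia = GenomicInterval("c", a.x1, a.x2)
            ib = GenomicInterval("c", b.x1, b.x2)
            assert giou(ia, ib) == pytest.approx(_giou_oracle(ia, ib))


def _rand_box(rng, span=40, size=25):
    x1 = int(rng.integers(0, span))
    y1 = int(rng.integers(0, span))
    return x1, y1, x1 + int(rng.integers(1, size)), y1 + int(rng.integers(1, size))


class TestMatching:
    def test_perfect_detections_all_paired(self):
        truths = [_box(0, 0, 10, 10), _box(20, 0, 30, 10)]
        dets = [_det(t, 0.9 - 0.1 * i) for i, t in enumerate(truths)]
        res = match_detections(dets, truths)
        assert sorted(res.pairs) == [(0, 0), (1, 1)]
        assert res.fp == [] and res.fn == []

    def test_missed_truth_counted_fn(self):
        res = match_detections([], [_box(0, 0, 10, 10)])
        assert res.fn == [0]

    def test_double_detection_higher_score_wins(self):
        truth = _box(0, 0, 10, 10)
        d_hi = _det(_box(0, 0, 10, 7), 0.9)   # IoU 0.7
        d_lo = _det(_box(0, 3, 10, 10), 0.8)  # IoU 0.7
        res = match_detections([d_lo, d_hi], [truth])
        assert res.pairs == [(1, 0)]
        assert res.fp == [0]


class TestPRCurve:
    def test_all_correct_ap_one(self):
        truths = [_box(0, 0, 10, 10), _box(20, 0, 30, 10)]
        dets = [_det(truths[0], 0.9), _det(truths[1], 0.8)]
        _, ap = pr_curve_and_map(dets, truths)
        assert ap == pytest.approx(1.0)

    def test_all_wrong_ap_zero(self):
        truths = [_box(0, 0, 10, 10)]
        dets = [_det(_box(50, 50, 60, 60), 0.9)]
        _, ap = pr_curve_and_map(dets, truths)
        assert ap == 0.0

    def test_hand_enumerated_tp_fp_tp_fixture(self):
        # ranks: TP (P=1, R=.5), FP (P=.5, R=.5), TP (P=2/3, R=1)
        # all-point interpolation: 0.5*1 + 0.5*(2/3) = 5/6
        truths = [_box(0, 0, 10, 10), _box(40, 0, 50, 10)]
        dets = [
            _det(truths[0], 0.9),
            _det(_box(70, 0, 80, 10), 0.8),
            _det(truths[1], 0.7),
        ]
        points, ap = pr_curve_and_map(dets, truths)
        assert points == [(0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3))]
        assert ap == pytest.approx(5 / 6)

    def test_no_truths_is_error(self):
        with pytest.raises(ValueError, match="no ground truths"):
            pr_curve_and_map([], [])


def _auroc_oracle(tp_scores, fp_scores):
    """Exhaustive Mann-Whitney pair counting with half credit for ties."""
    wins = sum(
        1.0 if t > f else (0.5 if t == f else 0.0)
        for t in tp_scores
        for f in fp_scores
    )
    return wins / (len(tp_scores) * len(fp_scores))


class TestROC:
    def test_perfect_separation(self):
        truths = [_box(0, 0, 10, 10), _box(20, 0, 30, 10)]
        dets = [
            _det(truths[0], 0.9),
            _det(truths[1], 0.8),
            _det(_box(50, 50, 60, 60), 0.2),
        ]
        _, auroc = roc_and_auroc(dets, truths)
        assert auroc == pytest.approx(1.0)

    def test_tied_tp_and_fp_give_half(self):
        truths = [_box(0, 0, 10, 10)]
        dets = [_det(truths[0], 0.5), _det(_box(50, 50, 60, 60), 0.5)]
        _, auroc = roc_and_auroc(dets, truths)
        assert auroc == pytest.approx(0.5)

    def test_single_class_is_error(self):
        truths = [_box(0, 0, 10, 10)]
        with pytest.raises(ValueError, match="one class"):
            roc_and_auroc([_det(truths[0], 0.9)], truths)

    def test_mixed_fixture_matches_mann_whitney(self):
        truths = [_box(0, 0, 10, 10), _box(20, 0, 30, 10)]
        dets = [
            _det(truths[0], 0.9),
            _det(_box(50, 50, 60, 60), 0.85),
            _det(truths[1], 0.6),
            _det(_box(70, 50, 80, 60), 0.3),
        ]
        _, auroc = roc_and_auroc(dets, truths)
        assert auroc == pytest.approx(_auroc_oracle([0.9, 0.6], [0.85, 0.3]))


class TestEvaluateCalls:
    def _calls(self, intervals, scores=None):
        scores = scores or [0.9] * len(intervals)
        return [MicroDomainCall(iv, s) for iv, s in zip(intervals, scores)]

    def test_identical_calls_perfect_report(self):
        truths = [
            GenomicInterval("chrX", 0, 100),
            GenomicInterval("chrX", 200, 300),
        ]
        rep = evaluate_calls(self._calls(truths), truths)
        assert rep.mean_giou == 1.0
        assert rep.f1 == 1.0
        assert rep.accuracy == 1.0

    def test_missed_truth_reduces_recall(self):
        truths = [GenomicInterval("chrX", i * 200, i * 200 + 100) for i in range(4)]
        rep = evaluate_calls(self._calls(truths[:3]), truths)
        assert rep.recall == pytest.approx(3 / 4)
        assert rep.fn == 1

    def test_shifted_calls_match_base_counting_oracle(self):
        truths = [
            GenomicInterval("chrX", 0, 1000),
            GenomicInterval("chrX", 2000, 3000),
        ]
        shifted = [
            GenomicInterval("chrX", 250, 1250),
            GenomicInterval("chrX", 2100, 3100),
        ]
        rep = evaluate_calls(self._calls(shifted), truths)
        want = sorted(_giou_oracle(s, t) for s, t in zip(shifted, truths))
        assert sorted(rep.per_domain_giou) == pytest.approx(want)
        assert rep.mean_giou == pytest.approx(float(np.mean(want)))

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError, match="empty truth"):
            evaluate_calls([], [])


class TestKFold:
    def test_fifty_items_five_even_folds(self):
        folds = kfold_split(list(range(50)), 5, seed=0)
        assert [len(f) for f in folds] == [10] * 5
        assert sorted(x for f in folds for x in f) == list(range(50))

    def test_k_one_single_fold(self):
        items = list("abcde")
        (fold,) = kfold_split(items, 1, seed=3)
        assert sorted(fold) == sorted(items)

    def test_same_seed_same_folds(self):
        a = kfold_split(list(range(23)), 4, seed=9)
        b = kfold_split(list(range(23)), 4, seed=9)
        assert a == b

    def test_sizes_differ_by_at_most_one(self):
        folds = kfold_split(list(range(23)), 4, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
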