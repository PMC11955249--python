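"""Metric semantics pinned against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from embryoseg.dataset_io import Box, ScoredBox
from embryoseg.metrics import (ConfusionCounts, average_precision, box_iou,
                               dice_coefficient, evaluate_dataset, hausdorff,
                               map_over_classes, match_detections,
                               precision_recall_f1)

from conftest import random_boxes, random_mask, random_scored_boxes


# ---------------------------------------------------------------------------
# brute-force oracles

def box_iou_by_pixels(a: Box, b: Box, lim: int = 64) -> float:
    """IoU by enumerating integer pixels under half-open semantics."""
    grid_a = np.zeros((lim, lim), dtype=bool)
    grid_b = np.zeros((lim, lim), dtype=bool)
    grid_a[int(a.y_min):int(a.y_max), int(a.x_min):int(a.x_max)] = True
    grid_b[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True
    union = (grid_a | grid_b).sum()
    return (grid_a & grid_b).sum() / union if union else 0.0


def dice_by_enumeration(a, b):
    tp = fp = fn = 0
    for x, y in zip(a.ravel(), b.ravel()):
        tp += x and y
        fp += x and not y
        fn += (not x) and y
    denom = fp + 2 * tp + fn
    return 2 * tp / denom if denom else 1.0


def hausdorff_all_pairs(p, g):
    pc = np.argwhere(p)
    gc = np.argwhere(g)
    if len(pc) == 0 and len(gc) == 0:
        return 0.0
    if len(pc) == 0 or len(gc) == 0:
        return float(np.hypot(*p.shape))
    d = np.sqrt(((pc[:, None, :] - gc[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def best_matching_by_enumeration(preds, gts, thresh=0.5):
    """Maximum-cardinality matching by exhaustive assignment search."""
    n, m = len(preds), len(gts)
    best = 0
    for k in range(min(n, m), 0, -1):
        for pred_idx in itertools.permutations(range(n), k):
            for gt_idx in itertools.combinations(range(m), k):
                if all(box_iou(preds[i].box, gts[j]) >= thresh
                       for i, j in zip(pred_idx, gt_idx)):
                    return k
        # no matching of size k found; try smaller
    return best


# ---------------------------------------------------------------------------

class TestBoxIoU:
    def test_identical(self):
        b = Box(2, 3, 10, 12)
        assert box_iou(b, b) == 1.0

    def test_disjoint(self):
        assert box_iou(Box(0, 0, 5, 5), Box(10, 10, 20, 20)) == 0.0

    def test_known_overlap(self):
        # inter 100, union 700
        assert box_iou(Box(0, 0, 20, 20), Box(10, 10, 30, 30)) == pytest.approx(1 / 7)

    def test_matches_pixel_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = random_boxes(rng, 2)
            assert box_iou(a, b) == pytest.approx(box_iou_by_pixels(a, b))


class TestMatching:
    def test_perfect(self):
        rng = np.random.default_rng(2)
        gts = random_boxes(rng, 4)
        preds = [ScoredBox(b, 0.5, "blastomere") for b in gts]
        counts, _ = match_detections(preds, gts)
        assert (counts.tp, counts.fp, counts.fn) == (4, 0, 0)

    def test_no_preds(self):
        rng = np.random.default_rng(3)
        gts = random_boxes(rng, 3)
        counts, _ = match_detections([], gts)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_duplicate_detection_is_fp(self):
        g1, g2 = Box(0, 0, 10, 10), Box(20, 20, 30, 30)
        preds = [ScoredBox(g1, 0.9, "blastomere"),
                 ScoredBox(g1, 0.8, "blastomere")]
        counts, _ = match_detections(preds, [g1, g2])
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_greedy_equals_exhaustive_tp(self):
        # greedy score-descending matching is standard; on random small
        # cases its TP count must match the exhaustive-search optimum
        rng = np.random.default_rng(4)
        agree = 0
        for _ in range(100):
            preds = random_scored_boxes(rng, int(rng.integers(0, 6)))
            gts = random_boxes(rng, int(rng.integers(0, 6)))
            counts, _ = match_detections(preds, gts)
            if counts.tp == best_matching_by_enumeration(preds, gts):
                agree += 1
        assert agree >= 97  # greedy is optimal except in rare adversarial ties


class TestPRF:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (0, 0, 0, (0.0, 0.0, 0.0)),
        (5, 0, 0, (1.0, 1.0, 1.0)),
        (3, 1, 2, (0.75, 0.6, 2 / 3)),
    ])
    def test_hand_values(self, tp, fp, fn, expected):
        got = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert got == pytest.approx(expected)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        rng = np.random.default_rng(5)
        gts = random_boxes(rng, 3)
        preds = [ScoredBox(b, 1.0 - 0.1 * i, "blastomere")
                 for i, b in enumerate(gts)]
        assert average_precision(preds, {"0": gts}) == pytest.approx(1.0)

    def test_all_wrong(self):
        gts = [Box(0, 0, 5, 5)]
        preds = [ScoredBox(Box(20, 20, 30, 30), 0.9, "blastomere")]
        assert average_precision(preds, {"0": gts}) == 0.0

    def test_envelope_integration(self):
        # 2 GTs, ranked [TP@.9, FP@.8, TP@.7]: AP = .5*1 + .5*(2/3) = 5/6
        g1, g2 = Box(0, 0, 10, 10), Box(20, 20, 30, 30)
        preds = [ScoredBox(g1, 0.9, "blastomere"),
                 ScoredBox(Box(40, 40, 50, 50), 0.8, "blastomere"),
                 ScoredBox(g2, 0.7, "blastomere")]
        assert average_precision(preds, {"0": [g1, g2]}) == pytest.approx(5 / 6)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            gts = random_boxes(rng, 4)
            preds = random_scored_boxes(rng, 6)
            ap1 = average_precision(preds, {"0": gts})
            squashed = [ScoredBox(p.box, p.score ** 3, p.category)
                        for p in preds]
            ap2 = average_precision(squashed, {"0": gts})
            assert ap1 == pytest.approx(ap2)

    def test_map_unweighted_mean(self):
        assert map_over_classes({"a": 0.5, "b": 1.0}) == pytest.approx(0.75)


class TestDice:
    def test_identical(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), dtype=bool); a[0, 0] = True
        b = np.zeros((8, 8), dtype=bool); b[7, 7] = True
        assert dice_coefficient(a, b) == 0.0

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice_coefficient(z, z) == 1.0

    def test_known_counts(self):
        a = np.zeros((4, 4), dtype=bool); a[0, :4] = True      # |a| = 4
        b = np.zeros((4, 4), dtype=bool); b[0, :2] = True      # 2 of them
        assert dice_coefficient(b, a) == pytest.approx(2 / 3)

    def test_matches_enumeration_and_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_mask(rng)
            b = random_mask(rng)
            d = dice_coefficient(a, b)
            assert d == pytest.approx(dice_by_enumeration(a, b))
            assert d == pytest.approx(dice_coefficient(b, a))


class TestHausdorff:
    def test_identity(self):
        rng = np.random.default_rng(8)
        m = random_mask(rng)
        assert hausdorff(m, m) == 0.0

    def test_single_pixel_pair(self):
        p = np.zeros((8, 8), dtype=bool); p[0, 0] = True
        g = np.zeros((8, 8), dtype=bool); g[3, 4] = True
        assert hausdorff(p, g) == pytest.approx(5.0)

    def test_offset_squares(self):
        p = np.zeros((10, 10), dtype=bool); p[0:3, 0:3] = True
        g = np.zeros((10, 10), dtype=bool); g[2:5, 0:3] = True
        assert hausdorff(p, g) == pytest.approx(2.0)

    def test_empty_conventions(self):
        z = np.zeros((3, 4), dtype=bool)
        m = z.copy(); m[1, 1] = True
        assert hausdorff(z, z) == 0.0
        assert hausdorff(m, z) == pytest.approx(np.hypot(3, 4))

    def test_matches_all_pairs_and_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = random_mask(rng, p=0.1)
            g = random_mask(rng, p=0.1)
            h = hausdorff(p, g)
            assert h == pytest.approx(hausdorff_all_pairs(p, g))
            assert h == pytest.approx(hausdorff(g, p))


class TestEvaluateDataset:
    def _gt(self, rng, n_images=3):
        gt = {}
        for i in range(n_images):
            boxes = [(b, "blastomere") for b in random_boxes(rng, 3)]
            gt[str(i)] = {"boxes": boxes,
                          "fragment_mask": random_mask(rng, (32, 32))}
        return gt

    def test_perfect_results(self):
        rng = np.random.default_rng(10)
        gt = self._gt(rng)
        results = {k: {"boxes": [ScoredBox(b, 1.0, c)
                                 for b, c in v["boxes"]],
                       "fragment_mask": v["fragment_mask"].copy()}
                   for k, v in gt.items()}
        rep = evaluate_dataset(results, gt)
        blast = rep.per_class["blastomere"]
        assert blast["precision"] == blast["recall"] == blast["ap"] == 1.0
        assert rep.mean_dice == 1.0
        assert rep.mean_hausdorff == 0.0

    def test_empty_results(self):
        rng = np.random.default_rng(11)
        gt = self._gt(rng)
        results = {k: {"boxes": []} for k in gt}
        rep = evaluate_dataset(results, gt)
        blast = rep.per_class["blastomere"]
        assert blast["precision"] == 0.0 and blast["recall"] == 0.0

    def test_pooled_counts_additive(self):
        rng = np.random.default_rng(12)
        gt = self._gt(rng, n_images=4)
        results = {k: {"boxes": random_scored_boxes(rng, 3)} for k in gt}
        rep = evaluate_dataset(results, gt)
        total = ConfusionCounts()
        for k in gt:
            counts, _ = match_detections(
                results[k]["boxes"], [b for b, _ in gt[k]["boxes"]])
            total = total + counts
        blast = rep.per_class["blastomere"]
        assert (blast["tp"], blast["fp"], blast["fn"]) == \
            (total.tp, total.fp, total.fn)

    def test_unknown_result_id_raises(self):
        with pytest.raises(KeyError):
            evaluate_dataset({"zz": {"boxes": []}}, {})
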