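"""Evaluation metrics: detection matching at IoU 0.5, precision/recall/
F1, average precision, pixel Dice and Hausdorff distance.

Conventions (pinned by tests):

* detection true positives require box IoU >= 0.5 with an unmatched
  ground-truth box, matched greedily in descending score;
* AP uses all-point interpolation (area under the precision envelope);
  mAP is the unweighted mean over classes;
* 0/0 rates are 0; Dice of two empty masks is 1;
* Hausdorff distance is the symmetric max-min Euclidean distance over
  the *full* foreground pixel sets (a boundary-only variant is exposed
  via ``boundary=True``); if exactly one set is empty the image diagonal
  is returned as a finite sentinel, and 0 if both are empty.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .dataset_io import Box, ScoredBox

__all__ = ["ConfusionCounts", "EvalReport", "box_iou", "match_detections",
           "precision_recall_f1", "average_precision", "map_over_classes",
           "dice_coefficient", "hausdorff", "evaluate_dataset"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def box_iou(a: Box, b: Box) -> float:
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return float(inter / (a.area + b.area - inter))


def match_detections(preds: list[ScoredBox], gts: list[Box],
                     iou_thresh: float = 0.5
                     ) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy score-descending matching; each GT matched at most once.

    Returns pooled counts and the list of (pred_index, gt_index) matches.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    taken = [False] * len(gts)
    matches = []
    for i in order:
        best_j, best_iou = -1, iou_thresh
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            iou = box_iou(preds[i].box, gt)
            if iou >= best_iou and iou > (0 if best_j < 0 else best_iou):
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[best_j] = True
            matches.append((i, best_j))
    tp = len(matches)
    return ConfusionCounts(tp=tp, fp=len(preds) - tp,
                           fn=len(gts) - tp), matches


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return precision, recall, f1


def average_precision(preds: list[ScoredBox], gts_by_image: dict,
                      iou_thresh: float = 0.5,
                      image_of: list | None = None) -> float:
    """All-point-interpolated AP for one class.

    ``preds`` is the pooled, scoreable detection list; ``gts_by_image``
    maps image id -> list of GT Boxes; ``image_of`` gives each
    prediction's image id (defaults to a single shared image "0").
    """
    n_gt = sum(len(v) for v in gts_by_image.values())
    if n_gt == 0:
        return 0.0
    if image_of is None:
        image_of = ["0"] * len(preds)
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    taken = {img: [False] * len(g) for img, g in gts_by_image.items()}
    tp_flags = []
    for i in order:
        img = image_of[i]
        gts = gts_by_image.get(img, [])
        best_j, best_iou = -1, iou_thresh
        for j, gt in enumerate(gts):
            if taken[img][j]:
                continue
            iou = box_iou(preds[i].box, gt)
            if iou >= best_iou and iou > (0 if best_j < 0 else best_iou):
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[img][best_j] = True
            tp_flags.append(1)
        else:
            tp_flags.append(0)
    if not tp_flags:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum([1 - t for t in tp_flags])
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (all-point interpolation)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def map_over_classes(per_class_ap: dict[str, float]) -> float:
    if not per_class_ap:
        return 0.0
    return float(np.mean(list(per_class_ap.values())))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    tp = np.logical_and(a, b).sum()
    fp = np.logical_and(a, ~b).sum()
    fn = np.logical_and(~a, b).sum()
    denom = fp + 2 * tp + fn
    if denom == 0:
        return 1.0  # agreement on absence
    return float(2 * tp / denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    return mask & ~ndimage.binary_erosion(mask)


def hausdorff(p: np.ndarray, g: np.ndarray, boundary: bool = False) -> float:
    p = np.asarray(p, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    if boundary:
        p, g = _boundary(p), _boundary(g)
    pc = np.argwhere(p).astype(float)
    gc = np.argwhere(g).astype(float)
    if pc.size == 0 and gc.size == 0:
        return 0.0
    if pc.size == 0 or gc.size == 0:
        h, w = p.shape
        return float(np.hypot(h, w))  # finite sentinel: image diagonal
    d1 = directed_hausdorff(pc, gc)[0]
    d2 = directed_hausdorff(gc, pc)[0]
    return float(max(d1, d2))


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_ap: float = 0.0
    mean_dice: float = 0.0
    mean_hausdorff: float = 0.0
    per_image: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_csv(self, path: str | Path) -> None:
        rows = self.per_image
        if not rows:
            Path(path).write_text("")
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)


def evaluate_dataset(results: dict, ground_truth: dict,
                     iou_thresh: float = 0.5) -> EvalReport:
    """Dataset-level report.

    ``results``: image id -> dict with keys ``boxes`` (list of ScoredBox,
    per class) and optionally ``fragment_mask``.
    ``ground_truth``: image id -> dict with ``boxes`` (list of
    (Box, category)) and optionally ``fragment_mask``.
    Detection precision/recall/F1 pool confusion counts over the split;
    AP pools ranked detections; Dice/Hausdorff are computed per image
    on the fragment masks and averaged.
    """
    missing = set(results) - set(ground_truth)
    if missing:
        raise KeyError(f"result ids missing from ground truth: {sorted(missing)}")

    classes = set()
    for gt in ground_truth.values():
        for _, cat in gt.get("boxes", []):
            classes.add(cat)
    for res in results.values():
        for sb in res.get("boxes", []):
            classes.add(sb.category)

    report = EvalReport()
    ap_per_class = {}
    for cls in sorted(classes):
        pooled = ConfusionCounts()
        all_preds: list[ScoredBox] = []
        image_of: list[str] = []
        gts_by_image: dict[str, list[Box]] = {}
        for img_id in sorted(ground_truth):
            gts = [b for b, cat in ground_truth[img_id].get("boxes", [])
                   if cat == cls]
            preds = [sb for sb in results.get(img_id, {}).get("boxes", [])
                     if sb.category == cls]
            gts_by_image[img_id] = gts
            counts, _ = match_detections(preds, gts, iou_thresh)
            pooled = pooled + counts
            all_preds.extend(preds)
            image_of.extend([img_id] * len(preds))
        p, r, f1 = precision_recall_f1(pooled)
        ap = average_precision(all_preds, gts_by_image, iou_thresh, image_of)
        ap_per_class[cls] = ap
        report.per_class[cls] = {"precision": p, "recall": r, "f1": f1,
                                 "ap": ap, "tp": pooled.tp, "fp": pooled.fp,
                                 "fn": pooled.fn}
    report.mean_ap = map_over_classes(ap_per_class)

    dices, hds = [], []
    for img_id in sorted(ground_truth):
        gt_frag = ground_truth[img_id].get("fragment_mask")
        res_frag = results.get(img_id, {}).get("fragment_mask")
        row = {"image_id": img_id}
        if gt_frag is not None and res_frag is not None:
            d = dice_coefficient(res_frag, gt_frag)
            h = hausdorff(res_frag, gt_frag)
            dices.append(d)
            hds.append(h)
            row.update(fragment_dice=d, fragment_hausdorff=h)
        report.per_image.append(row)
    if dices:
        report.mean_dice = float(np.mean(dices))
        report.mean_hausdorff = float(np.mean(hds))
    return report
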