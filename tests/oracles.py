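"""Brute-force reference implementations used to pin metric semantics.

These deliberately avoid the package's own code paths: IoU by pixel
enumeration, Dice by per-pixel confusion counting, Hausdorff by all-pairs
distances, matching re-derived greedily from pixel-enumerated IoUs, and
AP by explicit PR-point integration.
"""

import numpy as np


def box_iou_by_pixels(a, b, lim: int = 80) -> float:
    grid_a = np.zeros((lim, lim), dtype=bool)
    grid_b = np.zeros((lim, lim), dtype=bool)
    grid_a[int(a.y_min):int(a.y_max), int(a.x_min):int(a.x_max)] = True
    grid_b[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True
    union = (grid_a | grid_b).sum()
    return (grid_a & grid_b).sum() / union if union else 0.0


def dice_by_enumeration(a, b) -> float:
    tp = fp = fn = 0
    for x, y in zip(a.ravel(), b.ravel()):
        tp += bool(x) and bool(y)
        fp += bool(x) and not y
        fn += (not x) and bool(y)
    denom = fp + 2 * tp + fn
    return 2 * tp / denom if denom else 1.0


def hausdorff_all_pairs(p, g) -> float:
    pc = np.argwhere(p)
    gc = np.argwhere(g)
    if len(pc) == 0 and len(gc) == 0:
        return 0.0
    if len(pc) == 0 or len(gc) == 0:
        return float(np.hypot(*p.shape))
    d = np.sqrt(((pc[:, None, :] - gc[None, :, :]) ** 2).sum(-1))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def greedy_match_by_enumeration(preds, gts, thresh=0.5):
    """Score-descending greedy matching recomputed from pixel IoUs."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    taken = set()
    matches = []
    for i in order:
        candidates = []
        for j in range(len(gts)):
            if j in taken:
                continue
            iou = box_iou_by_pixels(preds[i].box, gts[j])
            if iou >= thresh:
                candidates.append((iou, j))
        if candidates:
            best = max(candidates, key=lambda t: t[0])
            taken.add(best[1])
            matches.append((i, best[1]))
    tp = len(matches)
    return tp, len(preds) - tp, len(gts) - tp


def ap_by_pr_integration(preds, gts, thresh=0.5) -> float:
    """All-point-interpolated AP from an explicitly built PR list."""
    n_gt = len(gts)
    if n_gt == 0:
        return 0.0
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    taken = set()
    flags = []
    for i in order:
        best, best_iou = None, thresh
        for j in range(len(gts)):
            if j in taken:
                continue
            iou = box_iou_by_pixels(preds[i].box, gts[j])
            if iou >= best_iou and (best is None or iou > best_iou):
                best, best_iou = j, iou
        if best is not None:
            taken.add(best)
            flags.append(True)
        else:
            flags.append(False)
    pr_points = []
    tp = fp = 0
    for f in flags:
        tp += f
        fp += not f
        pr_points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r, _ in pr_points:
        best_p = max((p for rr, p in pr_points if rr >= r), default=0.0)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap
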