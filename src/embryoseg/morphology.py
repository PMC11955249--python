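"""Clinical morphology summaries and keyframe extraction for time-lapse
sequences.

Each fused segmentation yields a per-frame report: blastomere count,
largest/smallest blastomere area relative to the image resolution, the
ratio of fragment area to the area of the *union* of blastomere masks
(the union, not the sum, so heavily overlapping cells do not deflate the
ratio), and the quadrant — relative to the embryo centroid — holding the
largest share of fragment area ("dominant position").

Across an ordered sequence, a keyframe marks a change of the blastomere
count: the count must differ from the previous stable count and persist
for at least ``persistence_k`` consecutive frames, which suppresses
single-frame detector flicker.  The first frame is always a keyframe.
The persistence rule is this package's definition of keyframes; it is
deliberately simple and documented rather than tuned.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .pipeline import FusedSegmentation

__all__ = ["MorphReport", "Keyframe", "morphology_report",
           "extract_keyframes", "video_report"]

QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass
class MorphReport:
    n_blastomeres: int
    max_rel_area: float
    min_rel_area: float
    frag_ratio: float          # math.inf when fragments but no blastomeres
    dominant_position: str     # NE / NW / SE / SW / none
    frame_index: int = 0
    fragment_centroid: tuple[float, float] | None = None


@dataclass
class Keyframe:
    frame_index: int
    count_before: int
    count_after: int
    report: MorphReport


def morphology_report(seg: FusedSegmentation,
                      image_size: tuple[int, int] | None = None,
                      frame_index: int = 0) -> MorphReport:
    h, w = image_size if image_size else seg.fragment_mask.shape
    total_px = h * w
    areas = [int(m.sum()) for m in seg.instance_masks]
    n = len(areas)
    max_rel = max(areas) / total_px if areas else 0.0
    min_rel = min(areas) / total_px if areas else 0.0

    union = np.zeros((h, w), dtype=bool)
    for m in seg.instance_masks:
        union |= m
    union_area = int(union.sum())
    frag_area = int(seg.fragment_mask.sum())
    if union_area > 0:
        frag_ratio = frag_area / union_area
    else:
        frag_ratio = math.inf if frag_area > 0 else 0.0

    dominant = "none"
    centroid = None
    if frag_area > 0:
        # centroid of all foreground (cells + fragments) = embryo centroid
        fg = union | seg.fragment_mask
        rr, cc = np.nonzero(fg)
        cy, cx = rr.mean(), cc.mean()
        fr, fc = np.nonzero(seg.fragment_mask)
        centroid = (float(fr.mean()), float(fc.mean()))
        north = fr < cy
        east = fc >= cx
        counts = {
            "NE": int(np.sum(north & east)),
            "NW": int(np.sum(north & ~east)),
            "SE": int(np.sum(~north & east)),
            "SW": int(np.sum(~north & ~east)),
        }
        dominant = max(QUADRANTS, key=lambda q: counts[q])
    return MorphReport(n_blastomeres=n, max_rel_area=max_rel,
                       min_rel_area=min_rel, frag_ratio=frag_ratio,
                       dominant_position=dominant, frame_index=frame_index,
                       fragment_centroid=centroid)


def extract_keyframes(reports: list[MorphReport],
                      persistence_k: int = 3) -> list[Keyframe]:
    """Keyframes = persistent changes of the blastomere count.

    A new count must hold for >= persistence_k consecutive frames (or to
    the end of the sequence, whichever comes first) to register.
    """
    if persistence_k < 1:
        raise ValueError("persistence_k must be >= 1")
    if not reports:
        return []
    counts = [r.n_blastomeres for r in reports]
    keyframes = [Keyframe(reports[0].frame_index, counts[0], counts[0],
                          reports[0])]
    stable = counts[0]
    i = 1
    while i < len(counts):
        c = counts[i]
        if c != stable:
            run = 1
            while i + run < len(counts) and counts[i + run] == c:
                run += 1
            if run >= persistence_k:
                keyframes.append(Keyframe(reports[i].frame_index, stable, c,
                                          reports[i]))
                stable = c
                i += run
                continue
            i += run  # transient flicker: skip it, stable count unchanged
        else:
            i += 1
    return keyframes


def video_report(frames, detector, net, out_dir: str | Path,
                 mode: str = "full", persistence_k: int = 3) -> dict:
    """Segment an ordered frame sequence and write timeline + keyframes.

    ``frames`` is a list of Image objects in temporal order.  Writes
    ``timeline.csv``, ``keyframes.json`` and one overlay PNG per
    keyframe under ``out_dir``.  Returns the keyframe summary.
    """
    from .pipeline import run_pipeline
    from .viz import save_overlay

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    segs = []
    for k, image in enumerate(frames):
        seg = run_pipeline(image, detector, net, mode=mode)
        reports.append(morphology_report(seg, frame_index=k))
        segs.append(seg)
    keyframes = extract_keyframes(reports, persistence_k=persistence_k)

    with open(out_dir / "timeline.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "n_blastomeres", "max_rel_area",
                         "min_rel_area", "frag_ratio", "dominant_position"])
        for r in reports:
            writer.writerow([r.frame_index, r.n_blastomeres,
                             f"{r.max_rel_area:.6f}", f"{r.min_rel_area:.6f}",
                             "inf" if math.isinf(r.frag_ratio)
                             else f"{r.frag_ratio:.6f}",
                             r.dominant_position])
    summary = {"keyframes": [
        {"frame_index": kf.frame_index, "count_before": kf.count_before,
         "count_after": kf.count_after,
         "report": {k: (None if isinstance(v, float) and math.isinf(v) else v)
                    for k, v in asdict(kf.report).items()}}
        for kf in keyframes]}
    with open(out_dir / "keyframes.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    for kf in keyframes:
        save_overlay(frames[kf.frame_index], segs[kf.frame_index],
                     out_dir / f"keyframe_{kf.frame_index:05d}.png",
                     report=kf.report)
    return summary
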