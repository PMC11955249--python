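"""Inference composition: detector -> instance branch, semantic branch,
and pixel-level mask fusion.

The fused result keeps every per-blastomere mask individually (heavily
overlapping cells are the norm, so no suppression is ever applied) plus
the shared fragment mask; the union of all of them is the final
foreground map, and a flattened label map is provided for rendering with
precedence fragment > higher-score instance > lower-score instance.

Three modes mirror the ablation surface of the method:

* ``full`` — detector boxes prompt the instance branch; fragments come
  from the semantic branch;
* ``no_semantic`` — fragments are also requested from the detector and
  segmented as instances (the semantic decoder is bypassed), so a
  detector that misses fragments yields an empty fragment mask;
* ``auto_prompt`` — no detector at all: a regular grid of fixed-size
  boxes prompts the instance branch and outputs carry no class identity.
  This is a deliberately simple stand-in for promptless automatic mask
  generation; it exists to reproduce the qualitative finding that
  without a detector the category of a mask cannot be identified.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .dataset_io import (AnnotatedFrame, Box, Image, ScoredBox,
                         pad_to_model_size, unpad_mask)
from .network import DualBranchNet, InstancePrediction
from .nn import no_grad

__all__ = ["FusedSegmentation", "DetectorInterface", "oracle_detector",
           "make_oracle_detector", "file_detector", "segment_instances",
           "segment_fragments", "fuse", "run_pipeline", "MODES"]

log = logging.getLogger(__name__)

MODES = ("full", "no_semantic", "auto_prompt")

DetectorInterface = Callable[[Image], list[ScoredBox]]


@dataclass
class FusedSegmentation:
    instance_masks: list[np.ndarray]
    instance_scores: list[float]
    instance_categories: list[str]
    fragment_mask: np.ndarray
    label_map: np.ndarray = field(init=False)
    final_mask: np.ndarray = field(init=False)

    def __post_init__(self):
        shapes = {m.shape for m in self.instance_masks}
        shapes.add(self.fragment_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"mask size mismatch: {shapes}")
        final = self.fragment_mask.copy()
        for m in self.instance_masks:
            final |= m
        self.final_mask = final
        # precedence: fragment > higher-score instance > lower-score one
        label = np.zeros(self.fragment_mask.shape, dtype=np.int32)
        order = np.argsort(self.instance_scores)  # ascending: low painted first
        for k in order:
            label[self.instance_masks[k]] = k + 1
        label[self.fragment_mask] = len(self.instance_masks) + 1
        self.label_map = label

    @property
    def n_instances(self) -> int:
        return len(self.instance_masks)


# ---------------------------------------------------------------------------
# detectors

def _components_boxes(mask: np.ndarray, min_area: int = 3) -> list[Box]:
    labeled, n = ndimage.label(mask)
    boxes = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        sub = labeled[sl]
        if (sub > 0).sum() < min_area:
            continue
        boxes.append(Box(float(sl[1].start), float(sl[0].start),
                         float(sl[1].stop), float(sl[0].stop)))
    return boxes


def oracle_detector(frame: AnnotatedFrame, jitter_px: float = 0.0,
                    drop_rate: float = 0.0, seed: int = 0,
                    include_fragments: bool = False) -> list[ScoredBox]:
    """Ground-truth-derived detections with controllable degradation.

    Corners are jittered uniformly in [-jitter_px, jitter_px]; each box
    is independently dropped with probability ``drop_rate``; scores
    decrease with the realized jitter magnitude.  Deterministic under
    ``seed``.  With ``include_fragments`` the connected components of
    the fragment mask are also emitted as fragment-class boxes (used by
    the no-semantic ablation).
    """
    rng = np.random.default_rng(seed)
    h, w = frame.image.shape
    entries: list[tuple[Box, str]] = [(b, c) for _, b, c in frame.instances]
    if include_fragments:
        entries += [(b, "fragment")
                    for b in _components_boxes(frame.fragment_mask)]
    out = []
    for box, category in entries:
        dropped = rng.uniform() < drop_rate
        deltas = rng.uniform(-jitter_px, jitter_px, size=4) if jitter_px else \
            np.zeros(4)
        if dropped:
            continue
        jittered = Box(
            min(box.x_min + deltas[0], box.x_max - 1.0 + deltas[2]),
            min(box.y_min + deltas[1], box.y_max - 1.0 + deltas[3]),
            max(box.x_max + deltas[2], box.x_min + 1.0 + deltas[0]),
            max(box.y_max + deltas[3], box.y_min + 1.0 + deltas[1]),
        ).clip(h, w)
        rel = np.abs(deltas).mean() / max(box.width, box.height)
        score = float(np.clip(1.0 - rel, 0.05, 1.0))
        out.append(ScoredBox(jittered, score, category))
    return out


def make_oracle_detector(frames_by_id: dict[str, AnnotatedFrame],
                         jitter_px: float = 0.0, drop_rate: float = 0.0,
                         seed: int = 0,
                         include_fragments: bool = False) -> DetectorInterface:
    """Wrap oracle_detector as an Image -> detections callable."""

    def detect(image: Image) -> list[ScoredBox]:
        frame = frames_by_id.get(image.id)
        if frame is None:
            log.warning("oracle detector knows no frame %r", image.id)
            return []
        # per-image seed (stable across processes) so jitter differs per image
        sub = (seed * 1_000_003
               + zlib.crc32(str(image.id).encode())) % (2 ** 31)
        return oracle_detector(frame, jitter_px=jitter_px,
                               drop_rate=drop_rate, seed=sub,
                               include_fragments=include_fragments)

    return detect


def file_detector(detections_path: str | Path) -> DetectorInterface:
    """Adapter for COCO detection-results JSON
    (list of {image_id, category_id, bbox xywh, score})."""
    with open(detections_path) as fh:
        dets = json.load(fh)
    id_to_cat = {1: "blastomere", 2: "fragment"}
    by_image: dict[str, list[ScoredBox]] = {}
    for d in dets:
        x, y, w, h = d["bbox"]
        sb = ScoredBox(Box.from_xywh(x, y, w, h), float(d["score"]),
                       id_to_cat.get(d.get("category_id", 1), "blastomere"))
        by_image.setdefault(str(d["image_id"]), []).append(sb)

    def detect(image: Image) -> list[ScoredBox]:
        if str(image.id) not in by_image:
            log.warning("no detections recorded for image %r", image.id)
            return []
        return by_image[str(image.id)]

    return detect


# ---------------------------------------------------------------------------
# branch inference

def segment_instances(image: Image, boxes: list[ScoredBox],
                      net: DualBranchNet) -> list[InstancePrediction]:
    """Run the instance branch: one unpadded mask per detector box."""
    if not boxes:
        return []
    frame = AnnotatedFrame(image=image)
    padded, t = pad_to_model_size(frame, net.cfg.target_size)
    with no_grad():
        emb = net.encode_image(padded.image)
        prompts = [net.encode_box_prompt(sb.box) for sb in boxes]
        preds = net.decode_instance_masks(emb, prompts)
    for pred, sb in zip(preds, boxes):
        pred.mask = unpad_mask(pred.mask, t)
        pred.logits = unpad_mask(pred.logits, t)
        pred.score = sb.score
        pred.logits_t = pred.iou_pred_t = None
    return preds


def segment_fragments(image: Image, net: DualBranchNet,
                      threshold: float = 0.5) -> np.ndarray:
    """Run the semantic branch: boolean fragment mask at image size."""
    frame = AnnotatedFrame(image=image)
    padded, t = pad_to_model_size(frame, net.cfg.target_size)
    with no_grad():
        emb = net.encode_image(padded.image)
        logits = net.decode_semantic(emb).data
    prob = 1.0 / (1.0 + np.exp(-logits))
    return unpad_mask(prob >= threshold, t)


def fuse(instances: list[InstancePrediction],
         fragment_mask: np.ndarray,
         categories: list[str] | None = None) -> FusedSegmentation:
    """Pixel-level union fusion; per-instance masks are kept distinct."""
    cats = categories or ["blastomere"] * len(instances)
    return FusedSegmentation(
        instance_masks=[p.mask for p in instances],
        instance_scores=[p.score for p in instances],
        instance_categories=list(cats),
        fragment_mask=np.asarray(fragment_mask, dtype=bool),
    )


def _grid_boxes(h: int, w: int, k: int = 4) -> list[ScoredBox]:
    """k x k regular grid of overlapping fixed-size boxes."""
    boxes = []
    bw, bh = 2.0 * w / (k + 1), 2.0 * h / (k + 1)
    for i in range(k):
        for j in range(k):
            cx = (j + 1) * w / (k + 1)
            cy = (i + 1) * h / (k + 1)
            box = Box(max(cx - bw / 2, 0.0), max(cy - bh / 2, 0.0),
                      min(cx + bw / 2, float(w)), min(cy + bh / 2, float(h)))
            boxes.append(ScoredBox(box, 0.5, "blastomere"))
    return boxes


def run_pipeline(image: Image, detector: DetectorInterface | None,
                 net: DualBranchNet, mode: str = "full",
                 grid_k: int = 4) -> FusedSegmentation:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "auto_prompt":
        h, w = image.shape
        boxes = _grid_boxes(h, w, k=grid_k)
        preds = segment_instances(image, boxes, net)
        # promptless proposals carry no class identity; nothing is a
        # recognised fragment, everything is an anonymous instance
        return fuse(preds, np.zeros(image.shape, dtype=bool),
                    categories=["blastomere"] * len(preds))

    detections = detector(image) if detector else []
    blasto = [sb for sb in detections if sb.category == "blastomere"]
    preds = segment_instances(image, blasto, net)

    if mode == "no_semantic":
        frag_boxes = [sb for sb in detections if sb.category == "fragment"]
        frag_preds = segment_instances(image, frag_boxes, net)
        frag_mask = np.zeros(image.shape, dtype=bool)
        for p in frag_preds:
            frag_mask |= p.mask
    else:
        frag_mask = segment_fragments(image, net)
    return fuse(preds, frag_mask)
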