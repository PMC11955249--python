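"""Geometry types and COCO-format I/O for embryo annotations.

Coordinate conventions used throughout the package:

* arrays are row-major, ``mask[row, col]``;
* boxes are 0-based half-open pixel intervals,
  ``[x_min, x_max) x [y_min, y_max)`` with ``x`` = column, ``y`` = row;
* COCO's ``[x, y, w, h]`` boxes and polygon vertex lists are converted at
  the file boundary and never used internally.

Binary masks are plain boolean numpy arrays.  Masks are written as
uncompressed COCO RLE (column-major counts starting with the zero run),
which round-trips pixel sets losslessly; polygons are accepted on read
and rasterized with pixel-centre point-in-polygon semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib.path import Path as MplPath

__all__ = [
    "Image", "Box", "ScoredBox", "AnnotatedFrame", "PadTransform",
    "CATEGORY_IDS", "mask_tight_box", "rasterize_polygon",
    "rle_encode", "rle_decode", "read_coco", "write_coco",
    "pad_to_model_size", "unpad_mask", "load_image",
]

CATEGORY_IDS = {"blastomere": 1, "fragment": 2}
_ID_TO_CATEGORY = {v: k for k, v in CATEGORY_IDS.items()}


@dataclass
class Image:
    """Intensity image in [0, 1], grayscale (H, W) or RGB (H, W, 3)."""

    pixels: np.ndarray
    id: str = "image"

    def __post_init__(self):
        self.pixels = np.clip(np.asarray(self.pixels, dtype=np.float32), 0.0, 1.0)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("Image must be HxW or HxWx3")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open pixel box [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, h: int, w: int) -> "Box":
        return Box(max(self.x_min, 0.0), max(self.y_min, 0.0),
                   min(self.x_max, float(w)), min(self.y_max, float(h)))

    def to_xywh(self) -> list[float]:
        return [self.x_min, self.y_min, self.width, self.height]

    @staticmethod
    def from_xywh(x: float, y: float, w: float, h: float) -> "Box":
        return Box(x, y, x + w, y + h)


@dataclass(frozen=True)
class ScoredBox:
    box: Box
    score: float
    category: str = "blastomere"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.category not in CATEGORY_IDS:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class AnnotatedFrame:
    """One image with blastomere instances and a merged fragment mask."""

    image: Image
    instances: list[tuple[np.ndarray, Box, str]] = field(default_factory=list)
    fragment_mask: np.ndarray | None = None

    def __post_init__(self):
        h, w = self.image.shape
        if self.fragment_mask is None:
            self.fragment_mask = np.zeros((h, w), dtype=bool)
        if self.fragment_mask.shape != (h, w):
            raise ValueError("fragment_mask shape differs from image")

    @property
    def instance_masks(self) -> list[np.ndarray]:
        return [m for m, _, _ in self.instances]

    @property
    def boxes(self) -> list[Box]:
        return [b for _, b, _ in self.instances]


@dataclass(frozen=True)
class PadTransform:
    """Bottom/right zero-padding from original_size up to target_size."""

    original_size: tuple[int, int]
    target_size: tuple[int, int]
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self):
        (h, w), (th, tw) = self.original_size, self.target_size
        if h > th or w > tw:
            raise ValueError("target smaller than original")


# ---------------------------------------------------------------------------
# mask geometry helpers

def mask_tight_box(mask: np.ndarray) -> Box:
    """Tight half-open bounding box of a non-empty boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return Box(float(cols[0]), float(rows[0]),
               float(cols[-1] + 1), float(rows[-1] + 1))


def rasterize_polygon(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon (COCO vertex order, (x, y) pairs) to a mask.

    A pixel (r, c) is foreground iff its centre (c + 0.5, r + 0.5) lies
    inside the polygon, so an integer-vertex square [5,15]x[5,15] covers
    exactly the half-open pixel box [5,15)x[5,15) (area 100).
    """
    h, w = shape
    xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
    path = MplPath(xy)
    x0 = max(int(np.floor(xy[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(xy[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(xy[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(xy[:, 1].max())) + 1, h)
    mask = np.zeros((h, w), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    cc, rr = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    inside = path.contains_points(pts).reshape(y1 - y0, x1 - x0)
    mask[y0:y1, x0:x1] = inside
    return mask


# ---------------------------------------------------------------------------
# uncompressed COCO RLE (column-major counts, first count is the zero run)

def rle_encode(mask: np.ndarray) -> dict:
    h, w = mask.shape
    flat = np.asarray(mask, dtype=np.uint8).ravel(order="F")
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    counts = runs.tolist()
    if flat[0] == 1:  # counts must start with the background run
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum {pos} != {h * w}")
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# COCO JSON

def load_image(path: str | Path, image_id: str | None = None) -> Image:
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return Image(arr, id=image_id or Path(path).stem)


def _segmentation_to_mask(seg, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(seg, dict):
        return rle_decode(seg)
    if isinstance(seg, list):
        mask = np.zeros(shape, dtype=bool)
        for poly in seg:
            mask |= rasterize_polygon(np.asarray(poly), shape)
        return mask
    raise ValueError(f"unsupported segmentation of type {type(seg)}")


def read_coco(images_dir: str | Path, annotations_path: str | Path
              ) -> list[AnnotatedFrame]:
    """Read a COCO annotation file into AnnotatedFrames.

    Polygons are rasterized; every fragment annotation is OR-ed into one
    semantic fragment mask per frame; blastomere boxes are recomputed as
    tight boxes of the rasterized masks (authoritative over stored xywh).
    """
    images_dir = Path(images_dir)
    with open(annotations_path) as fh:
        try:
            coco = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed COCO JSON {annotations_path}: {e}") from e

    cat_by_id = {}
    for cat in coco.get("categories", []):
        cat_by_id[cat["id"]] = cat["name"]
    unknown = [cid for cid, name in cat_by_id.items()
               if name not in CATEGORY_IDS]
    if unknown:
        raise ValueError(f"unknown category ids in annotations: {unknown}")

    anns_by_image: dict = {}
    for ann in coco.get("annotations", []):
        anns_by_image.setdefault(ann["image_id"], []).append(ann)

    frames = []
    for info in coco.get("images", []):
        path = images_dir / info["file_name"]
        if not path.exists():
            raise FileNotFoundError(f"image file missing: {path}")
        image = load_image(path, image_id=str(info["id"]))
        h, w = image.shape
        instances: list[tuple[np.ndarray, Box, str]] = []
        fragment_mask = np.zeros((h, w), dtype=bool)
        for ann in anns_by_image.get(info["id"], []):
            if ann["category_id"] not in cat_by_id:
                raise ValueError(f"annotation {ann.get('id')} has unknown "
                                 f"category_id {ann['category_id']}")
            name = cat_by_id[ann["category_id"]]
            mask = _segmentation_to_mask(ann["segmentation"], (h, w))
            if name == "fragment":
                fragment_mask |= mask
            else:
                if not mask.any():
                    continue
                instances.append((mask, mask_tight_box(mask), name))
        frames.append(AnnotatedFrame(image=image, instances=instances,
                                     fragment_mask=fragment_mask))
    return frames


def write_coco(frames: list[AnnotatedFrame], out_path: str | Path,
               file_names: list[str] | None = None) -> None:
    """Write AnnotatedFrames as COCO JSON with RLE segmentations."""
    ids = [f.image.id for f in frames]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in frames")
    images, annotations = [], []
    ann_id = 1
    for k, frame in enumerate(frames):
        h, w = frame.image.shape
        name = file_names[k] if file_names else f"{frame.image.id}.png"
        images.append({"id": frame.image.id, "file_name": name,
                       "height": int(h), "width": int(w)})
        for mask, box, category in frame.instances:
            annotations.append({
                "id": ann_id, "image_id": frame.image.id,
                "category_id": CATEGORY_IDS[category],
                "segmentation": rle_encode(mask),
                "area": int(mask.sum()),
                "bbox": [float(v) for v in box.to_xywh()],
                "iscrowd": 0,
            })
            ann_id += 1
        if frame.fragment_mask.any():
            annotations.append({
                "id": ann_id, "image_id": frame.image.id,
                "category_id": CATEGORY_IDS["fragment"],
                "segmentation": rle_encode(frame.fragment_mask),
                "area": int(frame.fragment_mask.sum()),
                "bbox": [float(v) for v in
                         mask_tight_box(frame.fragment_mask).to_xywh()],
                "iscrowd": 0,
            })
            ann_id += 1
    coco = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": cid, "name": name}
                       for name, cid in CATEGORY_IDS.items()],
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(coco, fh)


# ---------------------------------------------------------------------------
# padding convention: images smaller than the model input are zero-padded
# bottom/right, and predictions are cropped back (padding is loss-free)

def pad_to_model_size(frame: AnnotatedFrame, target: int
                      ) -> tuple[AnnotatedFrame, PadTransform]:
    h, w = frame.image.shape
    if target < max(h, w):
        raise ValueError(f"target {target} smaller than image {h}x{w}; "
                         "this pipeline pads, it never downscales")
    t = PadTransform((h, w), (target, target))
    pad_hw = ((0, target - h), (0, target - w))
    if frame.image.pixels.ndim == 3:
        pixels = np.pad(frame.image.pixels, pad_hw + ((0, 0),))
    else:
        pixels = np.pad(frame.image.pixels, pad_hw)
    instances = [(np.pad(m, pad_hw), b, c) for m, b, c in frame.instances]
    padded = AnnotatedFrame(
        image=Image(pixels, id=frame.image.id),
        instances=instances,
        fragment_mask=np.pad(frame.fragment_mask, pad_hw),
    )
    return padded, t


def unpad_mask(mask: np.ndarray, t: PadTransform) -> np.ndarray:
    if mask.shape != t.target_size:
        raise ValueError(f"mask shape {mask.shape} != padded size {t.target_size}")
    r0, c0 = t.offset
    h, w = t.original_size
    return mask[r0:r0 + h, c0:c0 + w]
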