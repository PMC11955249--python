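"""Synthetic cleavage-stage embryo scenes with pixel-perfect ground truth.

The generator emulates the structure of a cleavage-stage embryo
micrograph: a circular embryo bounded by the zona pellucida annulus,
1-8+ roughly round blastomeres that overlap heavily when crowded, and a
speckle of small anucleate fragments covering a controllable fraction of
the embryo area.  Every scene carries per-blastomere instance masks, a
semantic fragment mask, tight bounding boxes and the embryo geometry, so
training, evaluation and the morphology reports can all be exercised
without any external data.

Blastomeres are rendered as rotated ellipses with bounded eccentricity;
fragments are random-walk blobs.  Everything is driven by a single seed:
identical parameters give bit-identical scenes and images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage

from .dataset_io import (AnnotatedFrame, Box, Image, mask_tight_box,
                         write_coco)

__all__ = ["SceneParams", "SceneGroundTruth", "DatasetConfig",
           "generate_scene", "render_image", "generate_dataset"]


@dataclass(frozen=True)
class SceneParams:
    """Knobs of one synthetic scene; defaults mirror realistic conditions.

    ``overlap_target`` caps pairwise blastomere mask IoU and, when
    positive, the placer also *seeks* contact: each added cell must reach
    at least 60% of the cap with some already-placed neighbour, emulating
    the heavy clustering of real embryos.
    """

    image_size: int = 128
    n_blastomeres: int = 4
    blastomere_radius_range: tuple[float, float] = (0.32, 0.48)
    overlap_target: float = 0.5
    fragment_coverage: float = 0.1
    noise_sigma: float = 0.03
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_blastomeres < 1:
            raise ValueError("n_blastomeres must be >= 1")
        if not 0.0 <= self.fragment_coverage <= 0.5:
            raise ValueError("fragment_coverage must lie in [0, 0.5]")
        if not 0.0 <= self.overlap_target < 1.0:
            raise ValueError("overlap_target must lie in [0, 1)")
        lo, hi = self.blastomere_radius_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("blastomere_radius_range must satisfy 0<lo<=hi<1")


@dataclass
class SceneGroundTruth:
    instance_masks: list[np.ndarray]
    fragment_mask: np.ndarray
    boxes: list[Box]
    embryo_center: tuple[float, float]
    embryo_radius: float

    def frame(self, image: Image) -> AnnotatedFrame:
        return AnnotatedFrame(
            image=image,
            instances=[(m, b, "blastomere")
                       for m, b in zip(self.instance_masks, self.boxes)],
            fragment_mask=self.fragment_mask,
        )


def _ellipse_mask(size: int, center: tuple[float, float], a: float, b: float,
                  theta: float, clip_disk: np.ndarray) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask & clip_disk


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def _random_walk_blob(rng: np.random.Generator, size: int,
                      center: tuple[int, int], target_area: int) -> np.ndarray:
    """Irregular blob grown by a seeded random walk with dilation."""
    mask = np.zeros((size, size), dtype=bool)
    r, c = center
    steps = max(target_area // 2, 4)
    moves = rng.integers(0, 4, size=steps)
    dr = np.array([1, -1, 0, 0])[moves]
    dc = np.array([0, 0, 1, -1])[moves]
    rows = np.clip(r + np.cumsum(dr), 0, size - 1)
    cols = np.clip(c + np.cumsum(dc), 0, size - 1)
    mask[rows, cols] = True
    mask[r, c] = True
    # dilate until roughly the target area
    while mask.sum() < target_area:
        grown = ndimage.binary_dilation(mask)
        if grown.sum() == mask.sum():
            break
        mask = grown
    return mask


def generate_scene(params: SceneParams) -> SceneGroundTruth:
    """Place blastomeres and fragments inside the embryo disk.

    Raises RuntimeError when the requested geometry cannot be satisfied
    within a bounded number of rejection-sampling attempts.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    center = (size / 2.0, size / 2.0)
    embryo_radius = 0.42 * size
    rr, cc = np.mgrid[0:size, 0:size]
    embryo_disk = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2
                   <= embryo_radius ** 2)

    # cells shrink as the embryo cleaves: scale the radius range by n^-1/2
    lo, hi = params.blastomere_radius_range
    scale = embryo_radius * min(1.0, 1.35 / np.sqrt(params.n_blastomeres))
    ot = params.overlap_target

    masks: list[np.ndarray] = []
    max_attempts = 200
    for i in range(params.n_blastomeres):
        placed = False
        for _ in range(max_attempts):
            a = rng.uniform(lo, hi) * scale
            ecc = rng.uniform(0.0, 0.6)
            b = a * np.sqrt(1.0 - ecc ** 2)          # eccentricity <= 0.6
            theta = rng.uniform(0.0, np.pi)
            max_axis = max(a, b)
            # shrinking annulus around the embryo centre keeps cells packed
            r_max = max(embryo_radius - max_axis, 1.0)
            rad = r_max * np.sqrt(rng.uniform(0.0, 1.0)) * 0.9
            ang = rng.uniform(0.0, 2 * np.pi)
            cand_center = (center[0] + rad * np.sin(ang),
                           center[1] + rad * np.cos(ang))
            cand = _ellipse_mask(size, cand_center, a, b, theta, embryo_disk)
            if not cand.any():
                continue
            ious = [_mask_iou(cand, m) for m in masks]
            if ious and max(ious) > ot:
                continue
            if masks and ot > 0.0 and max(ious) < 0.6 * ot:
                continue  # must actually touch an existing cell
            masks.append(cand)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place blastomere {i + 1}/{params.n_blastomeres}: "
                "parameters too crowded (raise overlap_target or shrink cells)")

    fragment_mask = np.zeros((size, size), dtype=bool)
    if params.fragment_coverage > 0.0:
        embryo_area = int(embryo_disk.sum())
        target = params.fragment_coverage * embryo_area
        r_lo, r_hi = 3.0, 40.0  # blob equivalent radius in pixels
        for _ in range(max_attempts):
            current = int(fragment_mask.sum())
            if current >= 0.95 * target:
                break
            req = rng.uniform(r_lo, r_hi)
            blob_area = int(np.pi * req ** 2)
            blob_area = max(int(min(blob_area, 1.1 * target - current)), 3)
            rad = embryo_radius * np.sqrt(rng.uniform(0.0, 1.0)) * 0.9
            ang = rng.uniform(0.0, 2 * np.pi)
            br = int(round(center[0] + rad * np.sin(ang)))
            bc = int(round(center[1] + rad * np.cos(ang)))
            blob = _random_walk_blob(rng, size, (br, bc), blob_area)
            new = blob & embryo_disk & ~fragment_mask
            budget = int(1.1 * target) - current
            n_new = int(new.sum())
            if n_new > budget:
                # trim the freshly added pixels to budget, keeping the
                # blob compact (drop those farthest from its centre)
                rr_n, cc_n = np.nonzero(new)
                d2 = (rr_n - br) ** 2 + (cc_n - bc) ** 2
                keep = np.argsort(d2, kind="stable")[:budget]
                new[:] = False
                new[rr_n[keep], cc_n[keep]] = True
            fragment_mask |= new
        realized = int(fragment_mask.sum())
        if not 0.8 * target <= realized <= 1.2 * target:
            raise RuntimeError(
                f"fragment area {realized} outside +-20% of target {target:.0f}")

    boxes = [mask_tight_box(m) for m in masks]
    return SceneGroundTruth(instance_masks=masks, fragment_mask=fragment_mask,
                            boxes=boxes, embryo_center=center,
                            embryo_radius=embryo_radius)


def render_image(scene: SceneGroundTruth, params: SceneParams) -> Image:
    """Render a grayscale micrograph-like image of a scene.

    Intensity layout: dark background, mid-grey cytoplasm inside the
    embryo, bright blastomere bodies with darker rims, a bright zona
    pellucida annulus, and high-contrast fragment speckles; then Gaussian
    blur and additive Gaussian noise, all seeded.
    """
    size = params.image_size
    rng = np.random.default_rng(params.seed + 1_000_003)
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.sqrt((rr - scene.embryo_center[0]) ** 2
                   + (cc - scene.embryo_center[1]) ** 2)
    img = np.full((size, size), 0.15, dtype=np.float32)
    interior = dist <= scene.embryo_radius
    img[interior] = 0.35
    # zona pellucida annulus
    zona_w = max(size * 0.015, 1.5)
    zona = np.abs(dist - scene.embryo_radius) <= zona_w
    img[zona] = 0.55
    rim_px = max(int(round(size / 64)), 1)
    for mask in scene.instance_masks:
        body = ndimage.binary_erosion(mask, iterations=rim_px) if rim_px else mask
        rim = mask & ~body
        img[mask] = 0.70
        img[rim] = 0.30
        img[body] = 0.70
    img[scene.fragment_mask] = 0.90
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma,
                               size=img.shape).astype(np.float32)
    return Image(np.clip(img, 0.0, 1.0), id=f"scene-{params.seed}")


@dataclass(frozen=True)
class DatasetConfig:
    n_images: int = 20
    image_size: int = 128
    stage_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.25, 3: 0.15, 4: 0.25,
                                 5: 0.05, 6: 0.05, 7: 0.05, 8: 0.1})
    split_fraction: float = 0.8
    fragment_coverage: float = 0.1
    overlap_target: float = 0.5
    seed: int = 0

    def __post_init__(self):
        total = sum(self.stage_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("stage_distribution must sum to 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")


def _scene_params_for(config: DatasetConfig, n_cells: int, seed: int
                      ) -> SceneParams:
    return SceneParams(image_size=config.image_size, n_blastomeres=n_cells,
                       overlap_target=config.overlap_target,
                       fragment_coverage=config.fragment_coverage, seed=seed)


def generate_frames(config: DatasetConfig) -> list[AnnotatedFrame]:
    """Generate in-memory annotated frames following the stage mix."""
    rng = np.random.default_rng(config.seed)
    stages = sorted(config.stage_distribution)
    probs = np.array([config.stage_distribution[s] for s in stages])
    probs = probs / probs.sum()
    frames = []
    for k in range(config.n_images):
        n_cells = int(rng.choice(stages, p=probs))
        seed = int(rng.integers(0, 2 ** 31 - 1))
        for retry in range(10):
            try:
                params = _scene_params_for(config, n_cells, seed + retry)
                scene = generate_scene(params)
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(f"could not generate frame {k}")
        image = render_image(scene, params)
        image.id = f"{k:05d}"
        frames.append(scene.frame(image))
    return frames


def generate_dataset(config: DatasetConfig, out_dir: str | Path) -> dict:
    """Write a synthetic dataset: images/, annotations/{train,val}.json,
    and a manifest recording the generating configuration."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    ann_dir = out_dir / "annotations"
    images_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    frames = generate_frames(config)
    n_train = int(round(config.n_images * config.split_fraction))
    splits = {"train": frames[:n_train], "val": frames[n_train:]}
    for frame in frames:
        arr = (frame.image.pixels * 255).round().astype(np.uint8)
        iio.imwrite(images_dir / f"{frame.image.id}.png", arr)
    for name, split in splits.items():
        write_coco(split, ann_dir / f"{name}.json")
    manifest = {"config": {**asdict(config),
                           "stage_distribution":
                               {int(k): float(v) for k, v in
                                config.stage_distribution.items()}},
                "n_train": len(splits["train"]), "n_val": len(splits["val"])}
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
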