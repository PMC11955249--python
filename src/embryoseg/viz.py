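"""Overlay rendering: red blastomere boundaries, green fragment
boundaries, optional morphology text banner."""

from __future__ import annotations

import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .dataset_io import Image
from .pipeline import FusedSegmentation

__all__ = ["overlay_array", "save_overlay"]

RED = np.array([1.0, 0.1, 0.1], dtype=np.float32)
GREEN = np.array([0.1, 0.9, 0.2], dtype=np.float32)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def overlay_array(image: Image, seg: FusedSegmentation,
                  fill_alpha: float = 0.25) -> np.ndarray:
    px = image.pixels
    rgb = np.repeat(px[:, :, None], 3, axis=2) if px.ndim == 2 else px.copy()
    for mask in seg.instance_masks:
        rgb[mask] = (1 - fill_alpha) * rgb[mask] + fill_alpha * RED
        rgb[_boundary(mask)] = RED
    frag = seg.fragment_mask
    rgb[frag] = (1 - fill_alpha) * rgb[frag] + fill_alpha * GREEN
    rgb[_boundary(frag)] = GREEN
    return np.clip(rgb, 0.0, 1.0)


def save_overlay(image: Image, seg: FusedSegmentation, path: str | Path,
                 report=None) -> None:
    rgb = overlay_array(image, seg)
    if report is not None:
        # matplotlib renders the text banner with the four key quantities
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 4), dpi=max(rgb.shape[0] // 4, 64))
        ax.imshow(rgb)
        ratio = ("inf" if math.isinf(report.frag_ratio)
                 else f"{report.frag_ratio:.3f}")
        ax.set_title(
            f"n={report.n_blastomeres}  "
            f"max={report.max_rel_area:.3f} min={report.min_rel_area:.3f}\n"
            f"frag/blast={ratio}  frag pos={report.dominant_position}",
            fontsize=8)
        ax.axis("off")
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    else:
        iio.imwrite(Path(path), (rgb * 255).round().astype(np.uint8))
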