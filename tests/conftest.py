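import numpy as np
import pytest

from embryoseg.dataset_io import Box, ScoredBox
from embryoseg.network import NetworkConfig
from embryoseg.synthdata import DatasetConfig, SceneParams, generate_frames, \
    generate_scene, render_image

TINY = 64  # smallest legal model size: 4x4 embedding grid


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return NetworkConfig(embed_dim=16, encoder_width=4, target_size=TINY,
                         upblock_channels=(8, 8, 4, 4), seed=0)


@pytest.fixture(scope="session")
def small_scene():
    params = SceneParams(image_size=128, n_blastomeres=3, seed=42)
    scene = generate_scene(params)
    return params, scene


@pytest.fixture(scope="session")
def small_frame(small_scene):
    params, scene = small_scene
    return scene.frame(render_image(scene, params))


@pytest.fixture(scope="session")
def val_frames():
    """A handful of annotated frames for pipeline-level tests."""
    return generate_frames(DatasetConfig(n_images=6, image_size=128, seed=7))


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p


def random_boxes(rng, n, lim=32):
    boxes = []
    for _ in range(n):
        x0, y0 = rng.integers(0, lim - 2, size=2)
        w, h = rng.integers(1, lim // 2, size=2)
        boxes.append(Box(float(x0), float(y0),
                         float(min(x0 + w, lim)), float(min(y0 + h, lim))))
    return boxes


def random_scored_boxes(rng, n, lim=32):
    return [ScoredBox(b, float(rng.random()), "blastomere")
            for b in random_boxes(rng, n, lim)]
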