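"""COCO I/O, rasterization, RLE and padding round trips."""

import json

import numpy as np
import pytest

from embryoseg.dataset_io import (AnnotatedFrame, Box, Image, PadTransform,
                                  mask_tight_box, pad_to_model_size,
                                  rasterize_polygon, read_coco, rle_decode,
                                  rle_encode, unpad_mask, write_coco)
from embryoseg.synthdata import DatasetConfig, generate_dataset, \
    generate_frames


def point_in_polygon(x, y, poly):
    """Independent ray-casting oracle (crossing number)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xc:
                inside = not inside
    return inside


class TestGeometry:
    def test_box_degenerate_rejected(self):
        with pytest.raises(ValueError):
            Box(5, 5, 5, 10)

    def test_xywh_round_trip(self):
        b = Box(3, 4, 10, 20)
        assert Box.from_xywh(*b.to_xywh()) == b

    def test_tight_box(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        assert mask_tight_box(m) == Box(5, 5, 15, 15)


class TestRasterization:
    def test_square_polygon_area_and_box(self):
        poly = [5, 5, 15, 5, 15, 15, 5, 15]  # COCO flat xy list
        mask = rasterize_polygon(np.array(poly), (20, 20))
        assert mask.sum() == 100
        assert mask_tight_box(mask) == Box(5, 5, 15, 15)

    def test_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            # star-convex polygon so the oracle semantics are unambiguous
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
            radii = rng.uniform(3, 12, size=n)
            cx, cy = rng.uniform(10, 20, size=2)
            poly = [(cx + r * np.cos(a), cy + r * np.sin(a))
                    for a, r in zip(angles, radii)]
            mask = rasterize_polygon(np.array(poly).ravel(), (32, 32))
            oracle = np.zeros((32, 32), dtype=bool)
            for r in range(32):
                for c in range(32):
                    oracle[r, c] = point_in_polygon(c + 0.5, r + 0.5, poly)
            assert (mask == oracle).all()


class TestRLE:
    def test_round_trip_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.random((int(rng.integers(1, 24)),
                            int(rng.integers(1, 24)))) < 0.4
            assert (rle_decode(rle_encode(m)) == m).all()

    def test_counts_column_major_start_zero(self):
        m = np.array([[1, 0], [0, 0]], dtype=bool)
        rle = rle_encode(m)
        assert rle["counts"][0] == 0  # leading zero-run before the (0,0) px
        assert sum(rle["counts"]) == 4


class TestCocoRoundTrip:
    def test_write_read_preserves_pixel_sets(self, tmp_path):
        config = DatasetConfig(n_images=4, image_size=128, seed=3)
        frames = generate_frames(config)
        import imageio.v3 as iio
        img_dir = tmp_path / "images"
        img_dir.mkdir()
        for f in frames:
            iio.imwrite(img_dir / f"{f.image.id}.png",
                        (f.image.pixels * 255).round().astype(np.uint8))
        write_coco(frames, tmp_path / "ann.json")
        back = read_coco(img_dir, tmp_path / "ann.json")
        assert len(back) == len(frames)
        for orig, got in zip(frames, back):
            assert len(got.instances) == len(orig.instances)
            for (m1, b1, c1), (m2, b2, c2) in zip(orig.instances,
                                                  got.instances):
                assert (m1 == m2).all()
                assert b1 == b2 and c1 == c2
            assert (orig.fragment_mask == got.fragment_mask).all()

    def test_empty_frames_valid_coco(self, tmp_path):
        write_coco([], tmp_path / "empty.json")
        with open(tmp_path / "empty.json") as fh:
            coco = json.load(fh)
        assert coco["annotations"] == [] and coco["images"] == []
        assert {c["name"] for c in coco["categories"]} == \
            {"blastomere", "fragment"}

    def test_recorded_areas_equal_pixel_counts(self, tmp_path):
        frames = generate_frames(DatasetConfig(n_images=2, image_size=128,
                                               seed=4))
        write_coco(frames, tmp_path / "ann.json")
        with open(tmp_path / "ann.json") as fh:
            coco = json.load(fh)
        for ann in coco["annotations"]:
            assert ann["area"] == int(rle_decode(ann["segmentation"]).sum())

    def test_duplicate_ids_rejected(self, tmp_path):
        frames = generate_frames(DatasetConfig(n_images=1, image_size=128,
                                               seed=5)) * 2
        with pytest.raises(ValueError):
            write_coco(frames, tmp_path / "dup.json")

    def test_malformed_json(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError):
            read_coco(tmp_path, bad)

    def test_unknown_category(self, tmp_path):
        coco = {"images": [], "annotations": [],
                "categories": [{"id": 9, "name": "mitochondrion"}]}
        p = tmp_path / "weird.json"
        p.write_text(json.dumps(coco))
        with pytest.raises(ValueError):
            read_coco(tmp_path, p)

    def test_dataset_generation_round_trip(self, tmp_path):
        config = DatasetConfig(n_images=5, image_size=128, seed=6,
                               split_fraction=0.8)
        manifest = generate_dataset(config, tmp_path)
        assert manifest["n_train"] == 4 and manifest["n_val"] == 1
        frames = read_coco(tmp_path / "images",
                           tmp_path / "annotations" / "train.json")
        ref = generate_frames(config)[:4]
        for got, orig in zip(frames, ref):
            assert len(got.instances) == len(orig.instances)
            got_areas = sorted(int(m.sum()) for m in got.instance_masks)
            ref_areas = sorted(int(m.sum()) for m in orig.instance_masks)
            assert got_areas == ref_areas


class TestPadding:
    def _frame(self, h=100, w=80):
        rng = np.random.default_rng(2)
        img = Image(rng.random((h, w)), id="f")
        m = np.zeros((h, w), dtype=bool)
        m[10:30, 10:30] = True
        frag = np.zeros((h, w), dtype=bool)
        frag[50:60, 40:50] = True
        return AnnotatedFrame(image=img,
                              instances=[(m, mask_tight_box(m), "blastomere")],
                              fragment_mask=frag)

    def test_pad_shapes_and_offset(self):
        frame = self._frame()
        padded, t = pad_to_model_size(frame, 128)
        assert padded.image.shape == (128, 128)
        assert t.offset == (0, 0)
        assert t.original_size == (100, 80)
        # boxes anchored top-left: unchanged
        assert padded.boxes == frame.boxes

    def test_identity_when_target_equals_size(self):
        frame = self._frame(128, 128)
        padded, t = pad_to_model_size(frame, 128)
        assert (padded.image.pixels == frame.image.pixels).all()
        assert t.original_size == t.target_size

    def test_pad_unpad_identity_on_masks(self):
        frame = self._frame()
        padded, t = pad_to_model_size(frame, 128)
        for orig, pad in zip(frame.instance_masks, padded.instance_masks):
            assert (unpad_mask(pad, t) == orig).all()
        assert (unpad_mask(padded.fragment_mask, t)
                == frame.fragment_mask).all()

    def test_foreground_count_conserved(self):
        frame = self._frame()
        padded, t = pad_to_model_size(frame, 160)
        pm = padded.instance_masks[0]
        assert pm.sum() == unpad_mask(pm, t).sum()

    def test_target_too_small(self):
        with pytest.raises(ValueError):
            pad_to_model_size(self._frame(), 64)

    def test_unpad_size_mismatch(self):
        t = PadTransform((50, 50), (64, 64))
        with pytest.raises(ValueError):
            unpad_mask(np.zeros((50, 50), dtype=bool), t)

    def test_all_false_unpads_all_false(self):
        t = PadTransform((50, 40), (64, 64))
        out = unpad_mask(np.zeros((64, 64), dtype=bool), t)
        assert out.shape == (50, 40) and not out.any()
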