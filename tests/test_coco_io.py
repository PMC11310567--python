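"""COCO round-trips, polygon conversion and the 8:1:1 split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elaioscan import coco_io, seedsynth
from elaioscan.coco_io import (CocoDataset, SplitSpec, annotation_from_mask,
                               mask_to_polygon, polygon_to_mask, read_coco,
                               split_dataset, write_coco)
from elaioscan.evalmetrics import mask_iou


class TestPolygons:
    def test_filled_rectangle_is_single_4_vertex_ring_and_exact(self):
        m = np.zeros((20, 20), bool)
        m[3:13, 2:12] = True
        polys = mask_to_polygon(m)
        assert len(polys) == 1
        assert len(polys[0]) == 8  # 4 vertices
        assert (polygon_to_mask(polys, 20, 20) == m).all()

    def test_single_pixel_is_unit_square(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        polys = mask_to_polygon(m)
        assert len(polys) == 1 and len(polys[0]) == 8
        assert (polygon_to_mask(polys, 5, 5) == m).all()

    def test_mask_with_hole_roundtrips(self):
        m = np.zeros((15, 15), bool)
        m[2:13, 2:13] = True
        m[6:9, 6:9] = False
        polys = mask_to_polygon(m)
        assert len(polys) == 2  # outer contour + hole
        rt = polygon_to_mask(polys, 15, 15)
        assert mask_iou(rt, m) >= 0.99
        assert (rt == m).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_to_polygon(np.zeros((4, 4), bool))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_masks_roundtrip_exactly(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((18, 18)) < rng.uniform(0.2, 0.8)
        if not m.any():
            m[9, 9] = True
        rt = polygon_to_mask(mask_to_polygon(m), 18, 18)
        assert (rt == m).all()

    def test_rle_decoding(self):
        # column-major runs: 2 off, 3 on in a 2x3 mask
        m = coco_io.segmentation_to_mask(
            {"size": [2, 3], "counts": [2, 3, 1]}, 2, 3)
        expect = np.array([[False, True, True],
                           [False, True, False]])
        assert (m == expect).all()


def _toy_dataset(n_images=3, seeds_per=2):
    ds = CocoDataset()
    ann = 1
    rng = np.random.default_rng(0)
    for i in range(n_images):
        ds.images.append({"id": i + 1, "file_name": f"im{i}.png",
                          "width": 32, "height": 32})
        for _ in range(seeds_per):
            m = np.zeros((32, 32), bool)
            y, x = rng.integers(2, 20, 2)
            m[y:y + 6, x:x + 5] = True
            ds.annotations.append(annotation_from_mask(m, ann, i + 1))
            ann += 1
    return ds


class TestJsonRoundTrip:
    def test_write_read_write_is_byte_identical(self, tmp_path):
        ds = _toy_dataset()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_coco(ds, p1)
        write_coco(read_coco(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_annotations_roundtrip(self, tmp_path):
        ds = CocoDataset(images=[{"id": 1, "file_name": "x.png",
                                  "width": 8, "height": 8}])
        p = tmp_path / "e.json"
        write_coco(ds, p)
        back = read_coco(p)
        assert back.annotations == [] and len(back.images) == 1

    def test_generated_dataset_annotation_count(self, tmp_path):
        params = seedsynth.SceneParams(
            image_width_px=420, image_height_px=420, n_seeds=5,
            noise_sigma=0.0, rng_seed=5)
        _, ds = seedsynth.generate_dataset(2, params)
        assert len(ds.images) == 2
        assert len(ds.annotations) == 10
        # canonical serialization is deterministic across repeated calls
        p1, p2 = tmp_path / "1.json", tmp_path / "2.json"
        write_coco(ds, p1)
        _, ds2 = seedsynth.generate_dataset(2, params)
        write_coco(ds2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_inconsistent_bbox_rejected(self, tmp_path):
        ds = _toy_dataset(1, 1)
        ds.annotations[0].bbox = (0.0, 0.0, 30.0, 30.0)
        p = tmp_path / "bad.json"
        write_coco(ds, p)
        with pytest.raises(ValueError, match="bbox"):
            read_coco(p)


class TestSplit:
    def _images_only(self, n):
        return CocoDataset(images=[
            {"id": i, "file_name": f"{i}.png", "width": 4, "height": 4}
            for i in range(n)])

    def test_1000_images_split_800_100_100(self):
        parts = split_dataset(self._images_only(1000), SplitSpec(rng_seed=0))
        assert [len(p.images) for p in parts] == [800, 100, 100]

    def test_minimal_exact_case(self):
        parts = split_dataset(self._images_only(10), SplitSpec(rng_seed=1))
        assert [len(p.images) for p in parts] == [8, 1, 1]

    def test_deterministic_and_seed_sensitive(self):
        ds = self._images_only(50)
        a = split_dataset(ds, SplitSpec(rng_seed=3))
        b = split_dataset(ds, SplitSpec(rng_seed=3))
        c = split_dataset(ds, SplitSpec(rng_seed=4))
        assert [p.image_ids() for p in a] == [p.image_ids() for p in b]
        assert [len(p.images) for p in c] == [40, 5, 5]
        assert [sorted(p.image_ids()) for p in a] != \
            [sorted(p.image_ids()) for p in c]

    def test_partition_property_on_random_datasets(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            ds = self._images_only(n)
            parts = split_dataset(ds, SplitSpec(rng_seed=int(rng.integers(1e6))))
            ids = [set(p.image_ids()) for p in parts]
            assert ids[0] | ids[1] | ids[2] == set(range(n))
            assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
            assert sum(len(s) for s in ids) == n

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._images_only(2), SplitSpec())

    def test_annotations_follow_their_images(self):
        ds = _toy_dataset(12, 2)
        parts = split_dataset(ds, SplitSpec(rng_seed=0))
        for p in parts:
            ids = set(p.image_ids())
            assert all(a.image_id in ids for a in p.annotations)
        assert sum(len(p.annotations) for p in parts) == len(ds.annotations)
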