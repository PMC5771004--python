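"""Segmentation and feature extraction on constructed tiles."""

import colorsys
from collections import deque

import numpy as np
import pytest

from seedscore import (
    ALL_FEATURE_NAMES,
    HISTOGRAM_FEATURE_NAMES,
    OBJECT_FEATURE_NAMES,
    NoForegroundError,
    NoObjectError,
    ObjectMask,
    SeedImage,
    extract_features,
    extract_histograms,
    extract_object_features,
    label_objects,
    read_tile,
    select_central_object,
    threshold_image,
    tile_plate_image,
    write_tile,
)
from seedscore.seed_imaging import rgb_to_hsb255

from conftest import make_tile


class TestThreshold:
    def test_two_level_image_masks_dark_block(self):
        img = make_tile(block=(5, 10, 5, 10))
        mask = threshold_image(img, "otsu", "dark_object")
        expected = np.zeros((20, 20), bool)
        expected[5:10, 5:10] = True
        assert np.array_equal(mask, expected)

    def test_light_polarity_is_complement(self):
        img = make_tile(block=(5, 10, 5, 10))
        dark = threshold_image(img, "otsu", "dark_object")
        light = threshold_image(img, "otsu", "light_object")
        assert np.array_equal(light, ~dark)

    def test_otsu_matches_between_class_variance_scan(self):
        # Independent oracle: exhaustive argmax of between-class variance
        # over all 256 candidate thresholds, on a bimodal noisy image.
        rng = np.random.default_rng(3)
        grey = np.clip(
            np.where(
                rng.random((40, 40)) < 0.3,
                rng.normal(60, 12, (40, 40)),
                rng.normal(190, 10, (40, 40)),
            ),
            0,
            255,
        ).astype(np.uint8)
        img = SeedImage(np.stack([grey] * 3, axis=-1), "s0", time_index=1)

        counts = np.bincount(grey.ravel(), minlength=256).astype(float)
        total = counts.sum()
        best_t, best_var = None, -1.0
        for t in range(255):
            w0 = counts[: t + 1].sum()
            w1 = total - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (np.arange(t + 1) * counts[: t + 1]).sum() / w0
            mu1 = (np.arange(t + 1, 256) * counts[t + 1 :]).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
            if var > best_var:
                best_var, best_t = var, t

        mask = threshold_image(img, "otsu", "dark_object")
        assert np.array_equal(mask, grey <= best_t)

    def test_uniform_image_raises(self):
        img = make_tile(block=None)
        with pytest.raises(NoForegroundError):
            threshold_image(img, "otsu")

    def test_fixed_threshold(self):
        img = make_tile(block=(0, 4, 0, 4))
        mask = threshold_image(img, "fixed", "dark_object", fixed_threshold=100)
        assert mask.sum() == 16

    def test_fixed_requires_valid_threshold(self):
        with pytest.raises(ValueError):
            threshold_image(make_tile(block=(0, 4, 0, 4)), "fixed")


class TestLabelObjects:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        objs = label_objects(mask)
        assert sorted(o.pixel_count for o in objs) == [9, 16]

    def test_diagonal_touch_is_one_object(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only at the (3,3)/(4,4) corner
        assert len(label_objects(mask)) == 1

    def test_empty_mask_gives_no_objects(self):
        assert label_objects(np.zeros((10, 10), bool)) == []

    def test_component_count_matches_flood_fill_oracle(self):
        # Independent oracle: BFS flood fill with 8-neighbourhood.
        def flood_count(mask):
            seen = np.zeros_like(mask, bool)
            count = 0
            for r0, c0 in zip(*np.nonzero(mask)):
                if seen[r0, c0]:
                    continue
                count += 1
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                q.append((rr, cc))
            return count

        rng = np.random.default_rng(11)
        for _ in range(200):
            mask = rng.random((30, 30)) < 0.35
            assert len(label_objects(mask)) == flood_count(mask)


class TestSelectCentral:
    def _square(self, shape, r0, c0, size, label_id=1):
        m = np.zeros(shape, bool)
        m[r0 : r0 + size, c0 : c0 + size] = True
        return ObjectMask(mask=m, label_id=label_id)

    def test_single_object_selected(self):
        obj = self._square((21, 21), 2, 2, 3)
        assert select_central_object([obj], (21, 21)) is obj

    def test_distance_dominates_size(self):
        centre = self._square((41, 41), 18, 18, 5, label_id=1)  # area 25 at centre
        corner = self._square((41, 41), 0, 0, 20, label_id=2)  # area 400 in corner
        assert select_central_object([corner, centre], (41, 41)) is centre

    def test_equidistant_tie_broken_by_area(self):
        left = self._square((21, 21), 9, 2, 3, label_id=1)  # area 9
        right = self._square((21, 21), 8, 15, 5, label_id=2)  # area 25, same dist?
        # Build exact mirror-symmetric objects for a true tie.
        a = np.zeros((21, 21), bool)
        a[9:12, 2:5] = True  # centroid (10, 3)
        b = np.zeros((21, 21), bool)
        b[8:13, 15:20] = True  # centroid (10, 17): both 7 cols from centre col 10
        o1 = ObjectMask(mask=a, label_id=1)
        o2 = ObjectMask(mask=b, label_id=2)
        assert select_central_object([o1, o2], (21, 21)) is o2
        del left, right

    def test_permutation_invariant(self):
        objs = [
            self._square((41, 41), 5, 5, 4, 1),
            self._square((41, 41), 20, 18, 3, 2),
            self._square((41, 41), 30, 30, 6, 3),
        ]
        picked = {select_central_object(list(p), (41, 41)).label_id
                  for p in ([objs[0], objs[1], objs[2]],
                            [objs[2], objs[0], objs[1]],
                            [objs[1], objs[2], objs[0]])}
        assert len(picked) == 1

    def test_empty_list_raises(self):
        with pytest.raises(NoObjectError):
            select_central_object([], (10, 10))


class TestObjectFeatures:
    def _uniform_square_case(self):
        img = make_tile(h=11, w=11, background=220, block=(4, 7, 4, 7), value=100)
        obj = label_objects(threshold_image(img))[0]
        return extract_object_features(obj, img)

    def test_uniform_square_geometry_and_grey(self):
        f = self._uniform_square_case()
        assert f["area"] == 9
        assert f["mean_grey"] == 100
        assert f["sd_grey"] == 0
        assert (f["bbox_width"], f["bbox_height"]) == (3, 3)
        assert (f["centroid_x"], f["centroid_y"]) == (5, 5)
        assert f["dist_centroid_to_tile_center"] == 0
        assert f["extent"] == 1
        assert f["aspect_ratio"] == 1

    def test_uniform_square_perimeter_and_circularity(self):
        f = self._uniform_square_case()
        assert f["perimeter"] == 8  # all but the centre pixel touch outside
        assert f["circularity"] == pytest.approx(4 * np.pi * 9 / 64)

    def test_integrated_density_identity(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 255, size=(30, 30, 3), dtype=np.uint8)
        px[:5, :] = 255  # keep some light background
        img = SeedImage(px, "s0", time_index=1)
        mask = np.zeros((30, 30), bool)
        mask[10:20, 8:25] = True
        obj = ObjectMask(mask=mask, label_id=1)
        f = extract_object_features(obj, img)
        assert f["integrated_density"] == pytest.approx(f["area"] * f["mean_grey"])

    def test_single_pixel_object_is_finite(self):
        img = make_tile(h=11, w=11, block=(5, 6, 5, 6), value=10)
        obj = label_objects(threshold_image(img))[0]
        f = extract_object_features(obj, img)
        assert f["area"] == 1
        assert np.isfinite(f["elongation"])
        assert f["elongation"] == 1

    def test_grey_order_invariant(self):
        f = self._uniform_square_case()
        assert f["min_grey"] <= f["median_grey"] <= f["max_grey"]

    def test_exactly_25_named_features(self):
        f = self._uniform_square_case()
        assert tuple(f.keys()) == OBJECT_FEATURE_NAMES
        assert len(f) == 25


class TestHistograms:
    def test_uniform_grey_object(self):
        img = make_tile(h=12, w=12, block=(3, 5, 3, 8), value=100)  # 10 pixels
        obj = label_objects(threshold_image(img))[0]
        hist = extract_histograms(obj, img)
        r_block = hist[:256]
        assert r_block[100] == 10
        assert r_block.sum() == 10
        assert len(hist) == 1536

    def test_per_channel_sums_equal_pixel_count(self):
        rng = np.random.default_rng(9)
        px = rng.integers(0, 256, size=(25, 25, 3), dtype=np.uint8)
        img = SeedImage(px, "s0", time_index=1)
        mask = rng.random((25, 25)) < 0.4
        mask[0, 0] = True
        obj = ObjectMask(mask=mask, label_id=1)
        hist = extract_histograms(obj, img)
        for c in range(6):
            assert hist[256 * c : 256 * (c + 1)].sum() == obj.pixel_count

    def test_red_pixel_hsb(self):
        hsb = rgb_to_hsb255(np.array([[255, 0, 0]], dtype=np.uint8))
        assert hsb.tolist() == [[0, 255, 255]]

    def test_hsb_matches_colorsys_oracle(self):
        rng = np.random.default_rng(17)
        rgb = rng.integers(0, 256, size=(200, 3), dtype=np.uint8)
        hsb = rgb_to_hsb255(rgb)
        for (r, g, b), (h, s, v) in zip(rgb, hsb):
            oh, os_, ov = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
            assert h == round(oh * 255)
            assert s == round(os_ * 255)
            assert v == round(ov * 255)

    def test_whole_tile_mode_counts_every_pixel(self):
        img = make_tile(h=12, w=12, block=(3, 5, 3, 8), value=100)
        hist = extract_histograms(None, img, whole_tile=True)
        assert hist[:256].sum() == 12 * 12


class TestFullExtraction:
    def test_feature_vector_has_1561_entries(self):
        img = make_tile(h=30, w=30, block=(10, 20, 12, 22), value=60)
        f = extract_features(img)
        assert len(f) == 1561
        assert tuple(f.keys()) == ALL_FEATURE_NAMES
        assert len(HISTOGRAM_FEATURE_NAMES) == 1536

    def test_extraction_deterministic(self):
        img = make_tile(h=30, w=30, block=(10, 20, 12, 22), value=60)
        assert extract_features(img) == extract_features(img)

    def test_translation_invariance(self):
        base = make_tile(h=40, w=40, block=(5, 12, 5, 14), value=60)
        moved = make_tile(h=40, w=40, block=(20, 27, 18, 27), value=60)
        f0, f1 = extract_features(base), extract_features(moved)
        position = {
            "bbox_min_x", "bbox_min_y", "centroid_x", "centroid_y",
            "mass_center_x", "mass_center_y", "dist_centroid_to_tile_center",
            "dist_mass_center_to_tile_center",
        }
        for name in ALL_FEATURE_NAMES:
            if name not in position:
                assert f0[name] == pytest.approx(f1[name]), name


class TestTiling:
    def test_even_grid(self):
        plate = np.random.default_rng(0).integers(
            0, 256, size=(100, 100, 3), dtype=np.uint8
        )
        tiles = tile_plate_image(plate, 2, 2)
        assert len(tiles) == 4
        assert all(t.shape == (50, 50) for t in tiles)
        assert [t.seed_id for t in tiles] == ["r0c0", "r0c1", "r1c0", "r1c1"]

    def test_truncation(self):
        plate = np.zeros((101, 101, 3), dtype=np.uint8)
        tiles = tile_plate_image(plate, 2, 2)
        assert all(t.shape == (50, 50) for t in tiles)

    def test_reassembly_reproduces_source(self):
        plate = np.random.default_rng(1).integers(
            0, 256, size=(60, 80, 3), dtype=np.uint8
        )
        tiles = tile_plate_image(plate, 3, 4)
        rebuilt = np.vstack(
            [np.hstack([tiles[r * 4 + c].pixels for c in range(4)]) for r in range(3)]
        )
        assert np.array_equal(rebuilt, plate)

    def test_oversized_grid_raises(self):
        with pytest.raises(ValueError):
            tile_plate_image(np.zeros((4, 4, 3), dtype=np.uint8), 10, 10)


def test_tile_roundtrip_on_disk(tmp_path):
    img = make_tile(h=16, w=20, block=(4, 9, 6, 12), value=70, seed_id="sX", t=3)
    path = write_tile(img, tmp_path)
    back = read_tile(path)
    assert back.seed_id == "sX"
    assert back.time_index == 3
    assert np.array_equal(back.pixels, img.pixels)
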