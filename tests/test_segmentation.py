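"""Tiling, constrained per-tile thresholding, circle seeding and boundary
deduplication, checked against exhaustive oracles and rendering ground truth."""

import numpy as np
import pytest

from ttrack import (
    SceneConfig,
    SegmentationConfig,
    ValidationError,
    detect_circles,
    extract_components,
    generate_scene,
    render_timelapse,
    resolve_boundaries,
    segment_frame,
    threshold_tile,
    tile_frame,
)
from ttrack.segment import Tile, _otsu_threshold

from conftest import disk_frame, make_frame


def otsu_oracle(pixels):
    """Exhaustive between-class-variance scan over all cuts between
    consecutive observed values; midpoint of the best cut."""
    uniq = np.unique(pixels)
    if uniq.size < 2:
        return None
    x = pixels.astype(np.float64).ravel()
    best, best_t = -1.0, None
    for k in range(uniq.size - 1):
        t = (float(uniq[k]) + float(uniq[k + 1])) / 2.0
        lo, hi = x[x <= t], x[x > t]
        w0, w1 = lo.size / x.size, hi.size / x.size
        sigma_b = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sigma_b > best:
            best, best_t = sigma_b, t
    return best_t


class TestTiling:
    def test_64x64_partitions_into_four_tiles(self):
        frame = make_frame(np.zeros((64, 64), dtype=np.uint16))
        tiles = tile_frame(frame)
        assert [t.origin for t in tiles] == [(0, 0), (0, 32), (32, 0), (32, 32)]
        assert all(t.pixels.shape == (32, 32) for t in tiles)

    def test_single_tile_frame(self):
        tiles = tile_frame(make_frame(np.zeros((32, 32), dtype=np.uint16)))
        assert len(tiles) == 1 and tiles[0].origin == (0, 0)

    def test_truncated_edge_tiles(self):
        tiles = tile_frame(make_frame(np.zeros((70, 45), dtype=np.uint16)))
        assert len(tiles) == 6
        shapes = {t.origin: t.pixels.shape for t in tiles}
        assert shapes[(64, 0)] == (6, 32)
        assert shapes[(0, 32)] == (32, 13)
        assert shapes[(64, 32)] == (6, 13)

    def test_partition_covers_every_pixel_once(self, rng):
        frame = make_frame(rng.integers(0, 65536, size=(100, 67)).astype(np.uint16))
        cover = np.zeros(frame.shape, dtype=int)
        for t in tile_frame(frame):
            r0, c0 = t.origin
            h, w = t.pixels.shape
            cover[r0 : r0 + h, c0 : c0 + w] += 1
        assert (cover == 1).all()


class TestThresholdTile:
    def test_constant_tile_is_cell_free(self):
        tile = Tile(np.zeros((32, 32), dtype=np.uint16), (0, 0), 16)
        assert threshold_tile(tile) is None

    def test_block_tile_matches_exhaustive_oracle(self):
        pixels = np.full((32, 32), 10, dtype=np.uint16)
        pixels[4:12, 6:14] = 200
        tile = Tile(pixels, (0, 0), 16)
        mask, t = threshold_tile(tile, SegmentationConfig(threshold_bounds=(0.0, 1.0)))
        assert 10 < t < 200
        assert t == otsu_oracle(pixels)
        expect = np.zeros((32, 32), dtype=bool)
        expect[4:12, 6:14] = True
        np.testing.assert_array_equal(mask, expect)

    def test_bounds_exclude_out_of_range_threshold(self):
        pixels = np.full((32, 32), 10, dtype=np.uint16)
        pixels[4:12, 6:14] = 200
        tile = Tile(pixels, (0, 0), 16)
        assert threshold_tile(tile, SegmentationConfig(threshold_bounds=(0.9, 1.0))) is None

    def test_random_tiles_match_oracle_exactly(self, rng):
        for _ in range(50):
            pixels = rng.integers(0, 4000, size=(32, 32)).astype(np.uint16)
            assert _otsu_threshold(pixels) == otsu_oracle(pixels)


class TestExtractComponents:
    def _tile(self, mask_shape=(32, 32)):
        frame = make_frame(np.full((64, 64), 9, dtype=np.uint16))
        return Tile(frame.pixels[:32, :32], (0, 0), 16), frame

    def test_empty_mask_yields_nothing(self):
        tile, frame = self._tile()
        assert extract_components(np.zeros((32, 32), bool), tile, frame) == []

    def test_diagonally_touching_blobs_are_one_component(self):
        tile, frame = self._tile()
        mask = np.zeros((32, 32), bool)
        mask[2:6, 2:6] = True
        mask[6:10, 6:10] = True  # touches only at the (5,5)-(6,6) diagonal
        cfg = SegmentationConfig(min_component_area=1, max_component_area=450)
        dets = extract_components(mask, tile, frame, cfg)
        assert len(dets) == 1
        assert dets[0].features.area == 32

    def test_area_window_selects_single_component(self):
        tile, frame = self._tile()
        mask = np.zeros((32, 32), bool)
        mask[0, :3] = True  # area 3
        mask[5:15, 5:17] = True  # area 120
        mask[20:, :] = True  # area 384... needs > 450 to drop: widen
        mask2 = np.zeros((32, 32), bool)
        mask2[0, :3] = True
        mask2[5:15, 5:17] = True
        mask2[17:32, 0:32] = True  # area 480 > 450
        dets = extract_components(mask2, tile, frame, SegmentationConfig())
        assert len(dets) == 1
        assert dets[0].features.area == 120

    def test_shape_mismatch_rejected(self):
        tile, frame = self._tile()
        with pytest.raises(ValidationError, match="shape"):
            extract_components(np.zeros((8, 8), bool), tile, frame)


class TestDetectCircles:
    def test_blank_frame_has_no_seeds(self):
        assert detect_circles(make_frame(np.full((64, 64), 500, dtype=np.uint16))) == []

    def test_single_disk_seed_location_and_radius(self):
        frame = disk_frame((64, 64), [(16, 16, 8, 30000)], background=1000)
        seeds = detect_circles(frame, SegmentationConfig(circle_radius_range=(4, 16)))
        assert len(seeds) >= 1
        best = seeds[0]
        assert abs(best.row - 16) <= 1 and abs(best.col - 16) <= 1
        assert abs(best.radius - 8) <= 2

    def test_two_disks_yield_two_matched_seeds(self):
        frame = disk_frame((64, 64), [(20, 20, 6, 30000), (20, 44, 6, 30000)], background=1000)
        seeds = detect_circles(frame, SegmentationConfig(circle_radius_range=(4, 10)))
        hits = set()
        for s in seeds[:2]:
            for i, (r, c) in enumerate([(20, 20), (20, 44)]):
                if abs(s.row - r) <= 1 and abs(s.col - c) <= 1:
                    hits.add(i)
        assert hits == {0, 1}

    def test_invalid_radius_rejected(self):
        frame = disk_frame((64, 64), [(16, 16, 8, 30000)])
        with pytest.raises(ValidationError):
            detect_circles(frame, SegmentationConfig(circle_radius_range=(0, 8)))


def scene_frame(n_cells, seed, shape=(512, 512), **kw):
    cfg = SceneConfig(frame_shape=shape, n_frames=1, n_cells=n_cells, seed=seed, **kw)
    scene = generate_scene(cfg)
    tl, truth = render_timelapse(scene)
    return scene, tl.get(0)


class TestResolveBoundaries:
    def test_interior_detections_pass_through_unchanged(self):
        frame = disk_frame((64, 64), [(16, 16, 6, 30000)], background=1000)
        cfg = SegmentationConfig(min_component_area=20)
        dets = segment_frame(frame, cfg)
        out = resolve_boundaries(frame, dets, cfg)
        assert out == dets

    def test_disk_on_tile_boundary_detected_once(self):
        scene, frame = scene_frame(1, seed=5)
        scene.radii[:] = 8.0
        scene.centers[0, 0] = (200.0, 256.0)  # exactly on the col-256 tile edge
        tl, truth = render_timelapse(scene)
        dets = segment_frame(tl.get(0), SegmentationConfig())
        assert len(dets) == 1
        d = dets[0]
        assert np.hypot(d.features.centroid[0] - 200, d.features.centroid[1] - 256) < 1.5
        # the detection covers the whole disk, not one half
        mask = truth["masks"][0] > 0
        covered = {(r, c) for r, c in np.argwhere(mask)}
        got = set(map(tuple, d.pixel_set))
        assert len(got & covered) / len(covered) > 0.8
        cols = {c for _, c in got}
        assert min(cols) < 256 <= max(cols)

    def test_interior_detection_untouched_when_other_cell_on_boundary(self):
        scene, frame = scene_frame(2, seed=6)
        scene.radii[:] = 8.0
        scene.centers[0, 0] = (100.0, 100.0)
        scene.centers[0, 1] = (300.0, 288.0)
        tl, _ = render_timelapse(scene)
        frame = tl.get(0)
        cfg = SegmentationConfig()
        dets = segment_frame(frame, cfg)
        assert len(dets) == 2
        interior = min(
            dets, key=lambda d: np.hypot(d.features.centroid[0] - 100, d.features.centroid[1] - 100)
        )
        # recompute a first-pass-only segmentation on a frame without the
        # boundary cell: the interior record must be bit-identical
        scene2, _ = scene_frame(1, seed=6)
        scene2.radii[:] = 8.0
        scene2.centers[0, 0] = (100.0, 100.0)
        tl2, _ = render_timelapse(scene2)
        dets2 = segment_frame(tl2.get(0), cfg)
        # same pixels were rendered for the interior cell only if noise streams
        # align, so compare features structurally instead of raw noise
        assert interior.features.area > 150
        assert np.hypot(interior.features.centroid[0] - 100, interior.features.centroid[1] - 100) < 1.0


class TestSegmentFrame:
    def test_blank_frame_yields_nothing(self):
        assert segment_frame(make_frame(np.full((64, 64), 40, dtype=np.uint16))) == []

    def test_five_separated_disks_recovered_within_a_pixel(self):
        scene, frame = scene_frame(5, seed=11)
        dets = segment_frame(frame, SegmentationConfig())
        assert len(dets) == 5
        for i in range(5):
            truth_c = scene.centers[0, i]
            best = min(
                np.hypot(d.features.centroid[0] - truth_c[0], d.features.centroid[1] - truth_c[1])
                for d in dets
            )
            assert best <= 1.0

    def test_illumination_ramp_is_compensated(self):
        scene, frame = scene_frame(10, seed=12, illumination_gradient=0.3)
        dets = segment_frame(frame, SegmentationConfig())
        found = 0
        for i in range(10):
            truth_c = scene.centers[0, i]
            if any(
                np.hypot(d.features.centroid[0] - truth_c[0], d.features.centroid[1] - truth_c[1]) <= 2.0
                for d in dets
            ):
                found += 1
        assert found == 10

    def test_detections_are_pixel_disjoint_with_tight_boxes(self):
        _, frame = scene_frame(20, seed=13)
        dets = segment_frame(frame, SegmentationConfig())
        seen = set()
        for d in dets:
            px = set(map(tuple, d.pixel_set))
            assert not (px & seen)
            seen |= px
            rows = [p[0] for p in px]
            cols = [p[1] for p in px]
            assert d.bounding_box == (min(rows), min(cols), max(rows) + 1, max(cols) + 1)

    def test_translation_equivariance_for_interior_cell(self):
        base = np.full((128, 128), 1000.0)
        rr, cc = np.mgrid[0:128, 0:128]
        base[(rr - 40) ** 2 + (cc - 40) ** 2 <= 49] = 30000
        shifted = np.full((128, 128), 1000.0)
        shifted[(rr - 72) ** 2 + (cc - 72) ** 2 <= 49] = 30000
        cfg = SegmentationConfig(min_component_area=75, max_component_area=450)
        d0 = segment_frame(make_frame(base.astype(np.uint16)), cfg)
        d1 = segment_frame(make_frame(shifted.astype(np.uint16)), cfg)
        assert len(d0) == len(d1) == 1
        s0 = {(r + 32, c + 32) for r, c in map(tuple, d0[0].pixel_set)}
        assert s0 == set(map(tuple, d1[0].pixel_set))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"threshold_bounds": (0.9, 0.1)},
            {"circle_radius_range": (8, 4)},
            {"min_component_area": 450, "max_component_area": 75},
            {"boundary_margin": 40},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            SegmentationConfig(**kw)
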