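"""Per-cell measures against brute-force and independent-moment oracles."""

import math

import numpy as np
import pytest
from skimage.measure import regionprops

from ttrack import ValidationError, compute_distance, compute_region_features

from conftest import make_frame


def random_blob(rng, max_area=500, shape=(64, 64)):
    """Random 8-connected blob grown from a seed pixel."""
    target = int(rng.integers(5, max_area + 1))
    r, c = int(rng.integers(5, shape[0] - 5)), int(rng.integers(5, shape[1] - 5))
    pixels = {(r, c)}
    frontier = [(r, c)]
    while len(pixels) < target and frontier:
        pr, pc = frontier[int(rng.integers(len(frontier)))]
        dr, dc = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        q = (min(max(pr + dr, 0), shape[0] - 1), min(max(pc + dc, 0), shape[1] - 1))
        if q not in pixels:
            pixels.add(q)
            frontier.append(q)
    return pixels


def brute_force_features(pixel_set, frame):
    """Naive per-pixel reference for the exactly-checkable measures."""
    px = sorted(pixel_set)
    rows = [p[0] for p in px]
    cols = [p[1] for p in px]
    area = len(px)
    bbox_area = (max(rows) - min(rows) + 1) * (max(cols) - min(cols) + 1)
    vals = [int(frame.pixels[r, c]) for r, c in px]
    return {
        "area": area,
        "centroid": (sum(rows) / area, sum(cols) / area),
        "extent": area / bbox_area,
        "max_intensity": float(max(vals)),
        "mean_intensity": sum(vals) / area,
    }


def moment_axes_oracle(pixel_set):
    """Independent second-moment ellipse computation (eigendecomposition of
    the coordinate covariance with the 1/12 pixel term)."""
    coords = np.asarray(sorted(pixel_set), dtype=np.float64)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0] + np.diag([1 / 12, 1 / 12])
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major, minor = 4 * np.sqrt(eig[0]), 4 * np.sqrt(eig[1])
    ecc = math.sqrt(1 - eig[1] / eig[0])
    return major, minor, ecc


@pytest.fixture
def flat_frame(rng):
    return make_frame(rng.integers(0, 65536, size=(64, 64)).astype(np.uint16))


class TestExactCases:
    def test_filled_square(self):
        frame = make_frame(np.full((32, 32), 10, dtype=np.uint16))
        px = {(r, c) for r in range(3) for c in range(3)}
        f = compute_region_features(px, frame)
        assert f.area == 9
        assert f.extent == 1.0
        assert f.centroid == (1.0, 1.0)
        assert f.max_intensity == 10 and f.mean_intensity == 10
        assert f.eccentricity == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_line_is_highly_eccentric(self):
        frame = make_frame(np.zeros((32, 32), dtype=np.uint16))
        f = compute_region_features({(5, c) for c in range(10, 15)}, frame)
        assert f.area == 5
        assert f.extent == 1.0
        assert f.major_axis > f.minor_axis
        assert 0.9 < f.eccentricity < 1.0

    def test_digital_disk_approaches_circle(self):
        shape = (64, 64)
        frame = make_frame(np.zeros(shape, dtype=np.uint16))
        px = {
            (r, c)
            for r in range(shape[0])
            for c in range(shape[1])
            if (r - 30) ** 2 + (c - 30) ** 2 <= 100
        }
        f = compute_region_features(px, frame)
        assert f.area == len(px)
        assert f.eccentricity < 0.1
        assert f.perimeter == pytest.approx(2 * math.pi * 10, rel=0.10)

    def test_disk_area_ratio_and_eccentricity_shrink_with_radius(self):
        results = []
        for radius in (5, 10, 20):
            n = 2 * radius + 10
            frame = make_frame(np.zeros((max(n, 32), max(n, 32)), dtype=np.uint16))
            ctr = max(n, 32) // 2
            px = {
                (r, c)
                for r in range(max(n, 32))
                for c in range(max(n, 32))
                if (r - ctr) ** 2 + (c - ctr) ** 2 <= radius**2
            }
            f = compute_region_features(px, frame)
            results.append((abs(f.area / (math.pi * radius**2) - 1), f.eccentricity))
        ratios, eccs = zip(*results)
        assert ratios[2] < ratios[0] and ratios[2] < 0.03
        assert max(eccs) < 0.1


class TestOracleEquivalence:
    def test_random_blobs_match_brute_force_exactly(self, rng, flat_frame):
        for _ in range(100):
            px = random_blob(rng)
            f = compute_region_features(px, flat_frame)
            ref = brute_force_features(px, flat_frame)
            assert f.area == ref["area"]
            assert f.centroid == ref["centroid"]
            assert f.extent == ref["extent"]
            assert f.max_intensity == ref["max_intensity"]
            assert f.mean_intensity == ref["mean_intensity"]

    def test_moment_axes_match_independent_eigendecomposition(self, rng, flat_frame):
        for _ in range(50):
            px = random_blob(rng)
            f = compute_region_features(px, flat_frame)
            major, minor, ecc = moment_axes_oracle(px)
            assert f.major_axis == pytest.approx(major, rel=1e-9)
            assert f.minor_axis == pytest.approx(minor, rel=1e-9)
            assert f.eccentricity == pytest.approx(ecc, rel=1e-9, abs=1e-12)

    def test_matches_skimage_regionprops(self, rng, flat_frame):
        # independent cross-check against the standard library implementation
        # (perimeter and centroid only: the axis lengths here include the
        # 1/12 per-pixel variance term, which skimage's do not)
        for _ in range(20):
            px = random_blob(rng)
            coords = np.asarray(sorted(px))
            mask = np.zeros((64, 64), dtype=np.uint8)
            mask[coords[:, 0], coords[:, 1]] = 1
            rp = regionprops(mask, intensity_image=flat_frame.pixels)[0]
            f = compute_region_features(px, flat_frame)
            assert f.perimeter == pytest.approx(rp.perimeter, rel=1e-12)
            assert f.centroid == pytest.approx(tuple(rp.centroid), rel=1e-12)
            assert f.area == rp.area
            assert f.extent == pytest.approx(rp.extent, rel=1e-12)


class TestInvariances:
    def test_translation_leaves_all_but_centroid_unchanged(self, rng, flat_frame):
        uniform = make_frame(np.full((64, 64), 77, dtype=np.uint16))
        px = random_blob(rng, max_area=120, shape=(40, 40))
        f0 = compute_region_features(px, uniform)
        shifted = {(r + 13, c + 9) for r, c in px}
        f1 = compute_region_features(shifted, uniform)
        for name in ("area", "perimeter", "major_axis", "minor_axis", "extent", "eccentricity"):
            assert getattr(f0, name) == getattr(f1, name)
        assert f1.centroid == (f0.centroid[0] + 13, f0.centroid[1] + 9)

    def test_quarter_turn_preserves_axes(self, rng):
        uniform = make_frame(np.full((64, 64), 5, dtype=np.uint16))
        px = random_blob(rng, max_area=120, shape=(40, 40))
        rotated = {(c, 63 - r) for r, c in px}
        f0 = compute_region_features(px, uniform)
        f1 = compute_region_features(rotated, uniform)
        assert f0.major_axis == pytest.approx(f1.major_axis, rel=1e-9)
        assert f0.minor_axis == pytest.approx(f1.minor_axis, rel=1e-9)


class TestDistance:
    def test_examples(self):
        assert compute_distance((5.0, 5.0), (5.0, 5.0)) == 0.0
        assert compute_distance((0, 0), (3, 4)) == 5.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 100, size=(2, 2))
            assert compute_distance(a, b) == compute_distance(b, a)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            compute_distance((0.0, np.nan), (1.0, 1.0))


class TestValidation:
    def test_empty_pixel_set_rejected(self, flat_frame):
        with pytest.raises(ValidationError, match="empty"):
            compute_region_features(set(), flat_frame)

    def test_out_of_bounds_rejected(self, flat_frame):
        with pytest.raises(ValidationError, match="outside"):
            compute_region_features({(70, 2)}, flat_frame)

    def test_disconnected_set_rejected(self, flat_frame):
        with pytest.raises(ValidationError, match="connected"):
            compute_region_features({(1, 1), (10, 10)}, flat_frame)
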