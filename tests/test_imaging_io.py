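import logging

import numpy as np
import pytest
from PIL import Image

from tmipack import (GrayscaleImage, RoiPolygon, extract_roi, load_landmarks,
                     load_roi, read_grayscale, read_rgb, write_grayscale,
                     write_rgb)
from tmipack import fixtures as fx


class TestGrayscaleImage:
    def test_value_range_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            GrayscaleImage(np.array([[0, 256]]), bit_depth=8)
        with pytest.raises(ValueError, match="exceed"):
            GrayscaleImage(np.array([[-1]]), bit_depth=8)

    def test_minimal_image(self):
        img = GrayscaleImage(np.array([[0]]), bit_depth=8)
        assert img.count == 1 and img.levels == 256

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            GrayscaleImage(np.array([[0.5]]), bit_depth=8)


class TestRasterRoundTrip:
    @pytest.mark.parametrize("suffix", [".png", ".pgm"])
    def test_8bit_round_trip(self, tmp_path, suffix):
        img = fx.random_image(10, 10, 256, seed=0)
        path = tmp_path / f"img{suffix}"
        write_grayscale(img, path)
        back = read_grayscale(path)
        assert back.bit_depth == 8
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_high_depth_round_trip(self, tmp_path):
        img = fx.random_image(8, 8, 1024, seed=1)
        path = tmp_path / "deep.png"
        write_grayscale(img, path)
        back = read_grayscale(path, bit_depth=10)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_depth_override_rejects_out_of_range(self, tmp_path):
        img = fx.random_image(4, 4, 256, seed=2)
        path = tmp_path / "img.png"
        write_grayscale(img, path)
        with pytest.raises(ValueError, match="exceed"):
            read_grayscale(path, bit_depth=4)

    def test_rgb_round_trip(self, tmp_path, rng):
        arr = rng.integers(0, 256, (12, 7, 3)).astype(np.uint8)
        path = tmp_path / "rgb.png"
        write_rgb(arr, path)
        np.testing.assert_array_equal(read_rgb(path), arr)

    def test_jpeg_warns_lossy(self, tmp_path, caplog):
        img = fx.gradient_image(16, 16, 256)
        path = tmp_path / "img.jpg"
        Image.fromarray(img.pixels.astype(np.uint8)).save(path, quality=95)
        with caplog.at_level(logging.WARNING):
            read_grayscale(path)
        assert any("lossy" in r.message for r in caplog.records)

    def test_gray_rgb_collapses_but_color_rejected(self, tmp_path):
        gray = np.full((5, 5, 3), 77, dtype=np.uint8)
        p1 = tmp_path / "gray.png"
        write_rgb(gray, p1)
        assert (read_grayscale(p1).pixels == 77).all()
        color = gray.copy()
        color[0, 0, 1] = 99
        p2 = tmp_path / "color.png"
        write_rgb(color, p2)
        with pytest.raises(ValueError, match="not grayscale"):
            read_grayscale(p2)

    def test_unsupported_format(self, tmp_path):
        path = tmp_path / "img.bmp"
        Image.fromarray(np.zeros((4, 4), np.uint8)).save(path)
        with pytest.raises(ValueError, match="unsupported"):
            read_grayscale(path)


class TestRoiFiles:
    def test_rectangle_and_triangle(self, tmp_path):
        p = tmp_path / "roi.txt"
        p.write_text("# a rectangle\n0,0\n9,0\n9,9\n0,9\n")
        assert load_roi(p).vertices.shape == (4, 2)
        p.write_text("0,0\n4,0\n0,4\n")
        assert load_roi(p).vertices.shape == (3, 2)

    def test_too_few_vertices(self, tmp_path):
        p = tmp_path / "roi.txt"
        p.write_text("0,0\n1,1\n")
        with pytest.raises(ValueError, match="fewer than 3"):
            load_roi(p)

    def test_self_intersection_rejected(self, tmp_path):
        p = tmp_path / "roi.txt"
        p.write_text("0,0\n4,4\n4,0\n0,4\n")  # figure eight
        with pytest.raises(ValueError, match="self-intersecting"):
            load_roi(p)

    def test_landmark_file(self, tmp_path):
        p = tmp_path / "lm.txt"
        p.write_text("0,0,1,1\n5,2,6,3\n# comment\n")
        lm = load_landmarks(p)
        assert len(lm) == 2
        np.testing.assert_array_equal(lm.dst[1], [6, 3])


def brute_force_roi_count(image, polygon):
    """O(N*V) tally: pixel center inside-or-on-boundary test via shapely
    per point (the vectorized path never sees this loop)."""
    from shapely.geometry import Point
    poly = polygon.to_shapely()
    n = 0
    for yy in range(image.rows):
        for xx in range(image.cols):
            pt = Point(xx, yy)
            if poly.covers(pt):
                n += 1
    return n


class TestExtractRoi:
    def test_full_cover(self, small_random_image):
        roi = RoiPolygon([[0, 0], [19, 0], [19, 19], [0, 19]])
        assert extract_roi(small_random_image, roi).count == 400

    def test_empty_roi(self, small_random_image):
        roi = RoiPolygon([[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
        with pytest.raises(ValueError, match="empty ROI"):
            extract_roi(small_random_image, roi)

    def test_out_of_bounds(self, small_random_image):
        roi = RoiPolygon([[0, 0], [25, 0], [25, 25], [0, 25]])
        with pytest.raises(ValueError, match="outside"):
            extract_roi(small_random_image, roi)

    def test_matches_brute_force(self, rng):
        img = fx.random_image(20, 20, 256, seed=7)
        for _ in range(5):
            # random star-shaped simple polygon around a center
            cx, cy = rng.uniform(5, 14, 2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 8)))
            radii = rng.uniform(2, 5, angles.size)
            verts = np.column_stack([cx + radii * np.cos(angles),
                                     cy + radii * np.sin(angles)])
            verts = np.clip(verts, 0, 19)
            try:
                roi = RoiPolygon(verts)
            except ValueError:
                continue
            expected = brute_force_roi_count(img, roi)
            if expected == 0:
                continue
            assert extract_roi(img, roi).count == expected

    def test_invariant_under_vertex_rotation_and_reversal(self,
                                                          small_random_image):
        verts = np.array([[2, 1], [15, 3], [17, 16], [4, 12]], float)
        base = extract_roi(small_random_image, RoiPolygon(verts)).count
        for k in range(1, 4):
            rolled = np.roll(verts, k, axis=0)
            assert extract_roi(small_random_image,
                               RoiPolygon(rolled)).count == base
        assert extract_roi(small_random_image,
                           RoiPolygon(verts[::-1])).count == base
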