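import numpy as np
import pytest
from scipy import ndimage

from tilscope import (BinaryMask, RasterImage, SceneSpec, close_mask,
                      dice_coefficient, generate_scene, hsv_tissue_gate,
                      make_thumbnail, otsu_threshold, roberts_edges,
                      segment_tissue)
from tilscope.tissue_contour import CROSS_3X3, ContourConfig, to_grayscale


def brute_otsu(gray: np.ndarray) -> int:
    """Exhaustive 256-threshold search maximising between-class variance."""
    best, best_t = -1.0, 0
    flat = gray.ravel().astype(float)
    for t in range(256):
        c0, c1 = flat[flat <= t], flat[flat > t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0 = len(c0) / len(flat)
        sb = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if sb > best + 1e-12:
            best, best_t = sb, t
    return best_t


def brute_closing(grid: np.ndarray, n: int) -> np.ndarray:
    """Set-morphology oracle: n shifts-union dilations then n intersections."""
    offsets = [(r - 1, c - 1) for r in range(3) for c in range(3)
               if CROSS_3X3[r, c]]
    pad = 2 * n
    cur = np.pad(grid.astype(bool), pad)

    def dilate(m):
        out = np.zeros_like(m)
        for dr, dc in offsets:
            out |= np.roll(np.roll(m, dr, 0), dc, 1)
        return out

    def erode(m):
        out = np.ones_like(m)
        for dr, dc in offsets:
            out &= np.roll(np.roll(m, dr, 0), dc, 1)
        return out

    for _ in range(n):
        cur = dilate(cur)
    for _ in range(n):
        cur = erode(cur)
    return cur[pad:-pad, pad:-pad].astype(np.uint8)


class TestThumbnail:
    def test_20x_downsamples_by_8(self):
        img = RasterImage(np.full((800, 800, 3), 120, np.uint8),
                          magnification=20)
        thumb, scale = make_thumbnail(img)
        assert thumb.pixels.shape == (100, 100, 3) and scale == 8.0

    def test_native_magnification_is_identity(self):
        img = RasterImage(np.full((64, 64, 3), 99, np.uint8),
                          magnification=2.5)
        thumb, scale = make_thumbnail(img)
        assert scale == 1.0 and np.array_equal(thumb.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = RasterImage(np.full((160, 160, 3), 200, np.uint8),
                          magnification=10)
        thumb, _ = make_thumbnail(img)
        assert (thumb.pixels == 200).all()

    def test_missing_magnification_requires_factor(self):
        img = RasterImage(np.zeros((16, 16, 3), np.uint8))
        with pytest.raises(ValueError, match="magnification"):
            make_thumbnail(img)


class TestRoberts:
    def test_constant_image_gives_zero(self):
        assert (roberts_edges(np.full((10, 10), 42, np.uint8)) == 0).all()

    def test_vertical_step_response_is_local(self):
        g = np.zeros((10, 10), np.uint8)
        g[:, 5:] = 255
        mag = roberts_edges(g)
        nz_cols = np.unique(np.nonzero(mag)[1])
        assert set(nz_cols) <= {4, 5}

    def test_matches_direct_kernel_oracle(self, rng):
        g = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        mag = roberts_edges(g)
        gg = g.astype(float)
        for r in range(15):
            for c in range(15):
                d1 = gg[r, c] - gg[r + 1, c + 1]
                d2 = gg[r, c + 1] - gg[r + 1, c]
                expect = min(round(np.hypot(d1, d2)), 255)
                assert mag[r, c] == expect


class TestOtsu:
    def test_bimodal_60_40(self):
        g = np.zeros((10, 10), np.uint8)
        g.ravel()[:40] = 255
        t, mask = otsu_threshold(g)
        assert mask.area() == 40

    def test_two_level_image(self):
        g = np.full((8, 8), 10, np.uint8)
        g[:4] = 245
        t, mask = otsu_threshold(g)
        assert 10 <= t < 245
        assert np.array_equal(mask.grid, (g > 127).astype(np.uint8))

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            g = rng.integers(0, 256, (24, 24), dtype=np.uint8)
            t, _ = otsu_threshold(g)
            assert t == brute_otsu(g)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((5, 5), 7, np.uint8))


class TestClosing:
    def test_fills_single_hole(self):
        g = np.ones((7, 7), np.uint8)
        g[3, 3] = 0
        assert close_mask(BinaryMask(g)).grid[3, 3] == 1

    def test_empty_stays_empty(self):
        assert close_mask(BinaryMask(np.zeros((6, 6), np.uint8))).area() == 0

    def test_matches_set_morphology_oracle(self, rng):
        for _ in range(10):
            g = (rng.uniform(size=(32, 32)) < 0.35).astype(np.uint8)
            out = close_mask(BinaryMask(g))
            assert np.array_equal(out.grid, brute_closing(g, 3))

    def test_extensive_and_monotone(self, rng):
        a = (rng.uniform(size=(20, 20)) < 0.3).astype(np.uint8)
        b = (a | (rng.uniform(size=(20, 20)) < 0.2)).astype(np.uint8)
        ca, cb = close_mask(BinaryMask(a)), close_mask(BinaryMask(b))
        assert not (a & ~ca.grid).any()          # extensive
        assert not (ca.grid & ~cb.grid).any()    # monotone


class TestHsvGate:
    def test_white_excluded_by_saturation(self):
        img = RasterImage(np.full((12, 12, 3), 255, np.uint8))
        assert hsv_tissue_gate(img).area() == 0

    def test_pink_passes(self):
        img = RasterImage(np.tile(np.array([255, 192, 203], np.uint8),
                                  (12, 12, 1)))
        assert hsv_tissue_gate(img).grid.all()

    def test_pure_red_excluded_by_hue(self):
        img = RasterImage(np.tile(np.array([255, 0, 0], np.uint8),
                                  (12, 12, 1)))
        assert hsv_tissue_gate(img).area() == 0


class TestSegmentTissue:
    def test_synthetic_scene_dice(self, small_scene):
        mask, _ = segment_tissue(small_scene.image)
        assert dice_coefficient(mask, small_scene.tissue_truth) >= 0.95

    def test_pure_white_frame_warns_and_is_empty(self):
        img = RasterImage(np.full((64, 64, 3), 250, np.uint8),
                          magnification=2.5)
        with pytest.warns(UserWarning, match="empty"):
            mask, polys = segment_tissue(img)
        assert mask.area() == 0 and polys.polygons == []

    def test_two_blobs_give_two_polygons(self):
        for seed in range(30):
            s = generate_scene(SceneSpec(width=128, height=128, seed=seed,
                                         n_tissue_blobs=2,
                                         tissue_fraction=0.3))
            n_comp = ndimage.label(s.tissue_truth.grid,
                                   structure=np.ones((3, 3)))[1]
            if n_comp == 2:
                _, polys = segment_tissue(s.image)
                assert len(polys.polygons) == 2
                return
        pytest.skip("no seed produced two disjoint blobs")

    def test_and_semantics_subset_of_both_channels(self, small_scene):
        img = small_scene.image
        mask, _ = segment_tissue(img)
        thumb, _ = make_thumbnail(img)
        gate = hsv_tissue_gate(thumb)
        _, edge = otsu_threshold(roberts_edges(to_grayscale(thumb)))
        closed = close_mask(edge)
        assert not (mask.grid & ~gate.grid).any()
        assert not (mask.grid & ~closed.grid).any()

    def test_byte_determinism(self, small_scene):
        m1, _ = segment_tissue(small_scene.image)
        m2, _ = segment_tissue(small_scene.image)
        assert m1.grid.tobytes() == m2.grid.tobytes()

    def test_min_area_suppression(self, small_scene):
        cfg = ContourConfig(min_area=10 ** 6)
        mask, _ = segment_tissue(small_scene.image, cfg)
        assert mask.area() == 0
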