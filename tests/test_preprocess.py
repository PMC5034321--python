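"""Preprocessing chain: mirroring, levelling, filtering, extraction."""

import numpy as np
import pytest

from microwear.io import HeightMap
from microwear.iso25178 import std_direction
from microwear.preprocess import (
    PipelineConfig,
    denoise_median,
    extract_subsurfaces,
    gaussian_kernel,
    level_lsq_plane,
    mirror_x,
    preprocess_chain,
    smooth_gaussian,
)
from tests.conftest import cosine_ridges, make_grid


def _textured(n=64, seed=0, side=None):
    rng = np.random.default_rng(seed)
    x, y, dx = make_grid(n)
    z = 0.05 * np.sin(2 * x + y) + 0.01 * rng.standard_normal((n, n))
    m = HeightMap(z, dx, dx)
    if side:
        m.meta["side"] = side
    return m


class TestMirrorX:
    def test_involution_on_right_side(self):
        m = _textured(side="R")
        twice = mirror_x(mirror_x(m))
        np.testing.assert_array_equal(twice.heights, m.heights)

    def test_left_side_untouched(self):
        m = _textured(side="L")
        out = mirror_x(m)
        assert out is m

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            mirror_x(_textured())

    def test_lay_angle_reflected(self):
        """Mirroring in x maps a texture direction theta to 180 - theta."""
        m = cosine_ridges(30.0, n=128)
        m.meta["side"] = "R"
        mirrored = mirror_x(m)
        got = std_direction(level_lsq_plane(mirrored))
        assert got == pytest.approx(150.0, abs=1.0)


class TestLevelling:
    def test_pure_plane_maps_to_zero(self):
        x, y, dx = make_grid(64)
        m = HeightMap(0.3 * x - 0.2 * y + 5.0, dx, dx)
        out = level_lsq_plane(m)
        assert np.abs(out.heights).max() < 1e-9

    def test_projection_invariance(self):
        """level(s + plane) == level(s) for any surface and plane."""
        m = _textured(seed=3)
        x, y, dx = make_grid(64)
        shifted = m.copy_with(m.heights + 1.7 * x - 0.4 * y + 2.0)
        np.testing.assert_allclose(
            level_lsq_plane(shifted).heights, level_lsq_plane(m).heights, atol=1e-9
        )

    def test_residuals_satisfy_normal_equations(self):
        """Residuals orthogonal to 1, x and y (ordinary least squares)."""
        m = _textured(seed=5)
        out = level_lsq_plane(m)
        jj, ii = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        r = out.heights
        assert abs(r.sum()) < 1e-6
        assert abs((r * ii).sum()) < 1e-4
        assert abs((r * jj).sum()) < 1e-4

    def test_idempotent(self):
        m = _textured(seed=7)
        once = level_lsq_plane(m)
        twice = level_lsq_plane(once)
        np.testing.assert_allclose(twice.heights, once.heights, atol=1e-9)

    def test_collinear_points_rejected(self):
        z = np.zeros((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, :] = True  # a single row: collinear
        with pytest.raises(ValueError, match="collinear"):
            level_lsq_plane(HeightMap(z, 0.1, 0.1, valid_mask=mask))


class TestMedianFilter:
    def test_constant_unchanged(self):
        m = HeightMap(np.full((32, 32), 2.5), 0.1, 0.1)
        np.testing.assert_array_equal(denoise_median(m, 5).heights, m.heights)

    def test_single_spike_removed(self):
        z = np.zeros((32, 32))
        z[16, 16] = 10.0
        out = denoise_median(HeightMap(z, 0.1, 0.1), 5)
        assert np.abs(out.heights).max() == 0.0

    def test_matches_brute_force_window_median(self, rng):
        """Direct per-pixel windowed median oracle, reflect borders."""
        z = rng.standard_normal((20, 20))
        out = denoise_median(HeightMap(z, 0.1, 0.1), 3)
        zp = np.pad(z, 1, mode="symmetric")
        expected = np.empty_like(z)
        for j in range(20):
            for i in range(20):
                expected[j, i] = np.median(zp[j : j + 3, i : i + 3])
        np.testing.assert_allclose(out.heights, expected)

    def test_masked_pixels_excluded_from_ranking(self):
        z = np.zeros((16, 16))
        z[5, 5] = 100.0  # an invalid outlier must not leak into neighbours
        mask = np.ones((16, 16), bool)
        mask[5, 5] = False
        out = denoise_median(HeightMap(z, 0.1, 0.1, valid_mask=mask), 3)
        assert np.abs(out.heights[out.valid_mask]).max() == 0.0

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise_median(_textured(), 4)


class TestGaussianFilter:
    def test_constant_preserved(self):
        m = HeightMap(np.full((32, 32), 1.3), 0.1, 0.1)
        np.testing.assert_allclose(smooth_gaussian(m).heights, m.heights, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        z = np.zeros((31, 31))
        z[15, 15] = 1.0
        out = smooth_gaussian(HeightMap(z, 0.1, 0.1), 3, 0.8)
        np.testing.assert_allclose(
            out.heights[14:17, 14:17], gaussian_kernel(3, 0.8), atol=1e-12
        )
        assert out.heights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_preserved(self, rng):
        """Normalized symmetric kernel with reflective borders conserves mean."""
        z = rng.standard_normal((40, 40))
        m = HeightMap(z, 0.1, 0.1)
        out = smooth_gaussian(m, 3, 0.8)
        assert out.heights.mean() == pytest.approx(z.mean(), abs=1e-9)

    def test_mask_aware_renormalization(self):
        z = np.ones((16, 16))
        z[8, 8] = 1000.0  # invalid — must not bleed into valid neighbours
        mask = np.ones((16, 16), bool)
        mask[8, 8] = False
        out = smooth_gaussian(HeightMap(z, 0.1, 0.1, valid_mask=mask), 3, 0.8)
        assert np.allclose(out.heights[out.valid_mask], 1.0)


class TestExtraction:
    def test_four_windows_in_long_parent(self):
        z = np.zeros((24, 100))  # 12 x 50 µm at 0.5 µm/px
        m = HeightMap(z, 0.5, 0.5)
        subs = extract_subsurfaces(m, PipelineConfig(n_subsurfaces=4))
        assert len(subs) == 4
        assert all(s.map.nx == s.map.ny == 20 for s in subs)
        # non-overlapping along x
        origins = sorted(s.origin_um[0] for s in subs)
        assert all(b - a >= 10.0 for a, b in zip(origins, origins[1:]))

    def test_too_small_parent_rejected(self):
        m = HeightMap(np.zeros((18, 18)), 0.5, 0.5)  # 9 x 9 µm
        with pytest.raises(ValueError, match="µm"):
            extract_subsurfaces(m, PipelineConfig())

    def test_explicit_positions_honoured(self):
        m = HeightMap(np.arange(40 * 80, dtype=float).reshape(40, 80), 0.5, 0.5)
        subs = extract_subsurfaces(m, PipelineConfig(n_subsurfaces=2),
                                   positions=[(0.0, 0.0), (15.0, 5.0)])
        np.testing.assert_array_equal(subs[0].map.heights, m.heights[:20, :20])
        np.testing.assert_array_equal(subs[1].map.heights, m.heights[10:30, 30:50])


class TestChain:
    def test_plane_gives_all_zero_subsurfaces(self):
        y, x = np.meshgrid(np.arange(24) * 0.5, np.arange(100) * 0.5, indexing="ij")
        m = HeightMap(0.2 * x + 0.1 * y + 3.0, 0.5, 0.5, meta={"side": "L"})
        subs = preprocess_chain(m)
        assert len(subs) == 4
        for s in subs:
            assert np.abs(s.map.heights).max() < 1e-9

    def test_deterministic(self):
        m = _textured(n=80, seed=9, side="R")
        cfg = PipelineConfig(subsurface_size_um=3.0, n_subsurfaces=2)
        a = preprocess_chain(m, cfg)
        b = preprocess_chain(m, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.map.heights, sb.map.heights)

    def test_equals_manual_stage_composition(self):
        m = _textured(n=80, seed=11, side="R")
        cfg = PipelineConfig(subsurface_size_um=3.0, n_subsurfaces=2)
        chained = preprocess_chain(m, cfg)
        manual = []
        for sub in extract_subsurfaces(mirror_x(m), cfg):
            s = level_lsq_plane(sub.map)
            s = denoise_median(s, cfg.median_size)
            manual.append(smooth_gaussian(s, cfg.gaussian_size, cfg.gaussian_sigma))
        for sa, sb in zip(chained, manual):
            np.testing.assert_array_equal(sa.map.heights, sb.heights)

    def test_constant_offset_removed_by_chain(self):
        m = _textured(n=80, seed=13, side="L")
        cfg = PipelineConfig(subsurface_size_um=3.0, n_subsurfaces=2)
        shifted = m.copy_with(m.heights + 42.0)
        for sa, sb in zip(preprocess_chain(m, cfg), preprocess_chain(shifted, cfg)):
            np.testing.assert_allclose(sa.map.heights, sb.map.heights, atol=1e-9)

    def test_stages_preserve_shape_spacing_mask(self):
        m = _textured(n=64, seed=15)
        m.valid_mask[4, 4] = False
        for fn in (level_lsq_plane, lambda s: denoise_median(s, 5), smooth_gaussian):
            out = fn(m)
            assert out.heights.shape == m.heights.shape
            assert (out.dx, out.dy) == (m.dx, m.dy)
            np.testing.assert_array_equal(out.valid_mask, m.valid_mask)
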