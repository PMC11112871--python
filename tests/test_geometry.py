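"""Polar profiles, asymmetry, symmetrization, dimensions and circle metrics."""
import numpy as np
import pytest

import fruitmorph as fm
from fruitmorph.geometry import EmptyMaskError, mirror_mask, rotate_mask

from conftest import disk_mask, random_blob


def analytic_ellipse_profile(a: float, b: float) -> np.ndarray:
    theta = np.deg2rad(np.arange(360))
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def ellipse_mask(size: int, a: float, b: float) -> np.ndarray:
    c = (size - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return ((cc - c) / a) ** 2 + ((rr - c) / b) ** 2 <= 1.0


class TestToPolar:
    def test_disk_radius(self):
        profile = fm.to_polar(disk_mask(301, 100))
        assert np.all(np.abs(profile.radius_deg - 100.0) < 0.6)

    def test_ellipse_matches_analytic_form(self):
        profile = fm.to_polar(ellipse_mask(321, 120, 80))
        expected = analytic_ellipse_profile(120, 80)
        assert np.all(np.abs(profile.radius_deg - expected) < 1.0)

    def test_square_diagonal(self):
        mask = np.zeros((201, 201), dtype=bool)
        mask[50:150, 50:150] = True  # side 100
        profile = fm.to_polar(mask)
        assert profile.radius_deg[45] == pytest.approx(50 * np.sqrt(2), abs=1.0)

    def test_area_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            theta = np.deg2rad(np.arange(360))
            r = 70 * (1 + 0.1 * rng.standard_normal() * np.cos(2 * theta)
                      + 0.05 * rng.standard_normal() * np.sin(3 * theta))
            mask = np.zeros((201, 201), dtype=bool)
            rr, cc = np.meshgrid(np.arange(201), np.arange(201), indexing="ij")
            ang = np.degrees(np.arctan2(100 - rr, cc - 100)) % 360
            rlim = np.interp(ang, np.arange(360), r, period=360)
            mask = np.hypot(rr - 100, cc - 100) <= rlim
            profile = fm.to_polar(mask)
            assert profile.area() == pytest.approx(mask.sum(), rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            fm.to_polar(np.zeros((10, 10), dtype=bool))


class TestAsymmetry:
    def test_centered_disk_exactly_zero(self):
        assert fm.asymmetry_index(disk_mask(201, 80, (100, 100))) == 0.0

    def test_matches_pixel_oracle_on_random_blobs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            mask = random_blob(rng)
            # independent oracle: per-pixel mirror as a coordinate set, XOR
            # via symmetric set difference (no frame, so nothing clips)
            cx = np.average(np.nonzero(mask)[1])
            pixels = {(r, c) for r, c in zip(*np.nonzero(mask))}
            mirrored = {(r, int(np.rint(2 * cx - c))) for r, c in pixels}
            expected = len(pixels ^ mirrored) / (2.0 * mask.sum())
            assert fm.asymmetry_index(mask) == pytest.approx(expected, rel=1e-12)

    def test_right_triangle_strictly_positive(self):
        mask = np.tril(np.ones((60, 60), dtype=bool))
        assert fm.asymmetry_index(mask) > 0

    def test_translation_invariance(self):
        mask = random_blob(np.random.default_rng(4), size=48)
        padded = np.zeros((80, 80), dtype=bool)
        padded[10:58, 5:53] = mask
        shifted = np.roll(padded, (3, 7), axis=(0, 1))
        assert fm.asymmetry_index(padded) == pytest.approx(
            fm.asymmetry_index(shifted), abs=1e-12)

    def test_mirror_has_identical_index(self):
        mask = random_blob(np.random.default_rng(5), size=48)
        padded = np.pad(mask, ((0, 0), (48, 48)))  # room for the reflection
        assert fm.asymmetry_index(mirror_mask(padded)) == pytest.approx(
            fm.asymmetry_index(mask), abs=1e-9)


class TestSymmetrize:
    def test_recovers_applied_rotation(self):
        mask = ellipse_mask(261, 100, 60)
        rotated = rotate_mask(mask, 5.0)
        angle, _, residual = fm.symmetrize(rotated)
        assert angle == pytest.approx(-5.0, abs=0.5)
        assert residual < 0.01

    def test_symmetric_disk_identity(self):
        angle, _, asym = fm.symmetrize(disk_mask(201, 80, (100, 100)))
        assert angle == 0.0
        assert asym == 0.0

    def test_never_worse_than_no_rotation(self):
        mask = random_blob(np.random.default_rng(9), size=96, sigma=10)
        _, _, best = fm.symmetrize(mask)
        assert best <= fm.asymmetry_index(mask) + 1e-12

    def test_grid_minimum_near_finer_grid(self):
        mask = rotate_mask(ellipse_mask(161, 60, 40), 3.1)
        coarse, _, _ = fm.symmetrize(mask, step_deg=0.25)
        fine, _, _ = fm.symmetrize(mask, step_deg=0.025)
        assert abs(coarse - fine) <= 0.25 + 1e-9


class TestDimensions:
    def test_disk_extent(self):
        width, height = fm.dimensions(disk_mask(701, 300, (350, 350)), 0.01)
        assert width == pytest.approx(6.01, abs=0.02)
        assert height == pytest.approx(6.01, abs=0.02)

    def test_calibration_linearity(self):
        mask = ellipse_mask(161, 70, 50)
        w1, h1 = fm.dimensions(mask, 0.01)
        w2, h2 = fm.dimensions(mask, 0.02)
        assert (w2, h2) == (2 * w1, 2 * h1)


class TestTopCircles:
    def test_constant_profile(self):
        metrics = fm.top_circles(np.full(360, 250.0))
        assert metrics.radius_mean_px == 250
        assert metrics.radius_in_px == 250
        assert metrics.radius_circ_px == 250
        assert metrics.radius_std_nor == 0.0

    def test_ellipse_extremes_and_std(self):
        profile = fm.to_polar(ellipse_mask(321, 120, 80), view="top")
        metrics = fm.top_circles(profile)
        assert metrics.radius_circ_px == pytest.approx(120, abs=1)
        assert metrics.radius_in_px == pytest.approx(80, abs=1)
        analytic = analytic_ellipse_profile(120, 80)
        expected_std = np.std(analytic / analytic.mean(), ddof=1)
        assert metrics.radius_std_nor == pytest.approx(expected_std, abs=1e-3)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            r = np.exp(rng.normal(4, 0.2, 360))
            m = fm.top_circles(r)
            assert m.radius_in_px <= m.radius_mean_px <= m.radius_circ_px
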