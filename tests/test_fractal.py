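"""Blanket-method fractal dimension: closed forms, oracles, calibration."""
import numpy as np
import pytest

from fracperf.dce_preprocess import calibrate_intensity
from fracperf.fbm import fbm_surface
from fracperf.fractal_core import (blanket_surface_area, fd_from_areas,
                                   local_fd_map)
from fracperf.image import PerfusionImage


def brute_force_blanket(g: np.ndarray, scales) -> list[tuple[int, float]]:
    """Independent loop-based re-implementation of the blanket recursion."""
    g = np.asarray(g, dtype=float)
    nr, nc = g.shape
    u = g.copy()
    b = g.copy()
    out = []
    v_prev = 0.0
    for eps in scales:
        un = np.empty_like(u)
        bn = np.empty_like(b)
        for i in range(nr):
            for j in range(nc):
                nb_u = [u[i + di, j + dj] for di, dj in
                        ((-1, 0), (1, 0), (0, -1), (0, 1))
                        if 0 <= i + di < nr and 0 <= j + dj < nc]
                nb_b = [b[i + di, j + dj] for di, dj in
                        ((-1, 0), (1, 0), (0, -1), (0, 1))
                        if 0 <= i + di < nr and 0 <= j + dj < nc]
                un[i, j] = max(u[i, j] + 1, max(nb_u))
                bn[i, j] = min(b[i, j] - 1, min(nb_b))
        u, b = un, bn
        v = float(np.sum(u - b))
        out.append((eps, (v - v_prev) / 2.0))
        v_prev = v
    return out


class TestBlanketAreas:
    def test_constant_image_has_topological_area(self):
        """A flat surface's blanket area equals the pixel count at every scale."""
        areas = blanket_surface_area(np.full((20, 20), 5.0), [1, 2, 3, 4])
        for _, a in areas:
            assert a == pytest.approx(400.0)

    def test_ramp_area_constant_over_scale(self):
        """A unit-slope ramp is smooth: A(eps) does not grow with eps."""
        g = np.tile(np.arange(8, dtype=float), (8, 1))
        areas = blanket_surface_area(g, [1, 2, 3])
        vals = [a for _, a in areas]
        assert max(vals) - min(vals) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_loop(self, seed):
        """Vectorized recursion equals the explicit-loop oracle exactly."""
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 256, (16, 16)).astype(float)
        fast = blanket_surface_area(g, [1, 2, 3, 4])
        slow = brute_force_blanket(g, [1, 2, 3, 4])
        for (e1, a1), (e2, a2) in zip(fast, slow):
            assert e1 == e2 and a1 == pytest.approx(a2, abs=1e-9)

    def test_nonconsecutive_scales_rejected(self):
        with pytest.raises(ValueError):
            blanket_surface_area(np.zeros((16, 16)), [2, 3, 4])


class TestFdFromAreas:
    def test_constant_areas_give_smooth_limit(self):
        fd, r2 = fd_from_areas([(1, 10.0), (2, 10.0), (3, 10.0)])
        assert fd == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_inverse_scaling_gives_embedding_limit(self):
        areas = [(e, 1.0 / e) for e in (1, 2, 3, 4)]
        fd, r2 = fd_from_areas(areas)
        assert fd == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_too_few_scales_rejected(self):
        with pytest.raises(ValueError):
            fd_from_areas([(1, 5.0), (2, 4.0)])

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            fd_from_areas([(1, 5.0), (2, 0.0), (3, 1.0)])


class TestFbmCalibration:
    @pytest.mark.parametrize("hurst", [0.2, 0.5, 0.8])
    def test_global_fd_tracks_hurst(self, hurst):
        """Blanket FD of calibrated fBm surfaces approaches 3 - H (5 seeds;
        the full 20-seed calibration runs in the acceptance suite)."""
        fds = []
        for seed in range(5):
            surf = fbm_surface(257, hurst, seed)
            img = calibrate_intensity(PerfusionImage(surf, 1.0))
            fds.append(fd_from_areas(blanket_surface_area(img.pixels, [1, 2, 3, 4]))[0])
        assert np.mean(fds) == pytest.approx(3.0 - hurst, abs=0.15)


class TestLocalFdMap:
    def test_constant_image_maps_to_two(self):
        fdm = local_fd_map(np.full((40, 40), 9.0), window_radius=3,
                           scales=(1, 2, 3, 4))
        assert np.all(fdm.fd[fdm.valid_mask] == pytest.approx(2.0))
        assert fdm.clip_fraction == 0.0

    def test_validity_margin(self):
        fdm = local_fd_map(np.zeros((40, 40)), window_radius=3, scales=(1, 2, 3, 4))
        margin = 3 + 4
        assert not fdm.valid_mask[:margin].any()
        assert not fdm.valid_mask[:, -margin:].any()
        assert fdm.valid_mask[margin:-margin, margin:-margin].all()

    def test_matches_naive_per_pixel_loop(self):
        """Vectorized local map equals per-pixel windowed regression."""
        rng = np.random.default_rng(12)
        g = rng.integers(0, 256, (32, 32)).astype(float)
        wr, scales = 3, (1, 2, 3)
        fdm = local_fd_map(g, window_radius=wr, scales=scales)
        # naive: run the (already brute-force-verified) global recursion,
        # then per-pixel window sums and an explicit regression
        u = g.copy()
        b = g.copy()
        stacks = []
        for _ in scales:
            un = np.empty_like(u)
            bn = np.empty_like(b)
            nr, nc = g.shape
            for i in range(nr):
                for j in range(nc):
                    nb = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                    nb = [(a, c) for a, c in nb if 0 <= a < nr and 0 <= c < nc]
                    un[i, j] = max(u[i, j] + 1, max(u[a, c] for a, c in nb))
                    bn[i, j] = min(b[i, j] - 1, min(b[a, c] for a, c in nb))
            u, b = un, bn
            stacks.append(u - b)
        margin = wr + max(scales)
        x = np.log(np.array(scales, float))
        for i in range(margin, 32 - margin):
            for j in range(margin, 32 - margin, 3):
                v_prev = 0.0
                logA = []
                for k in range(len(scales)):
                    win = stacks[k][i - wr:i + wr + 1, j - wr:j + wr + 1]
                    v = float(win.sum())
                    logA.append(np.log((v - v_prev) / 2.0))
                    v_prev = v
                slope = np.polyfit(x, logA, 1)[0]
                expected = min(max(2.0 - slope, 2.0), 3.0)
                assert fdm.fd[i, j] == pytest.approx(expected, abs=1e-9)

    def test_affine_invariance_after_calibration(self):
        """The calibrate -> FD pipeline is invariant to affine intensity maps."""
        rng = np.random.default_rng(4)
        g = rng.random((48, 48)) * 60 + 20
        a = local_fd_map(calibrate_intensity(PerfusionImage(g, 1.5)))
        b = local_fd_map(calibrate_intensity(PerfusionImage(3.7 * g + 11.0, 1.5)))
        np.testing.assert_allclose(a.fd[a.valid_mask], b.fd[b.valid_mask],
                                   atol=1e-9)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            local_fd_map(np.zeros((64, 64)), window_radius=1, scales=(1, 2, 3, 4))
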