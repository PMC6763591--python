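"""Fractal-dimension, Hurst, Hoelder and texton texture representations."""

import numpy as np
import pytest

from gliomics.fractal import (
    TextureMap,
    _prism_cell_areas,
    default_filter_bank,
    holder_map,
    map_region_stats,
    mbm_hurst_map,
    ptpsa_map,
    texton_histogram,
    texton_label_map,
)


def brute_force_ptpsa_fd(window_img: np.ndarray, scales=(1, 2, 4)) -> float:
    """Independent oracle: explicit triangle sums + polyfit log-log slope."""

    def tri(p1, p2, p3):
        u, v = np.subtract(p2, p1), np.subtract(p3, p1)
        return 0.5 * np.linalg.norm(np.cross(u, v))

    side = window_img.shape[0] - 1
    areas = []
    for s in scales:
        total = 0.0
        for i in range(0, side, s):
            for j in range(0, side, s):
                a = window_img[i, j]
                b = window_img[i, j + s]
                c = window_img[i + s, j]
                d = window_img[i + s, j + s]
                e = (a + b + c + d) / 4.0
                A, B = (0, 0, a), (s, 0, b)
                C, D = (0, s, c), (s, s, d)
                E = (s / 2, s / 2, e)
                total += tri(A, B, E) + tri(B, D, E) + tri(D, C, E) + tri(C, A, E)
        areas.append(total)
    slope = np.polyfit(np.log(scales), np.log(areas), 1)[0]
    return float(np.clip(2.0 - slope, 2.0, 3.0))


class TestPtpsa:
    def test_flat_image_fd_exactly_two(self):
        fd = ptpsa_map(np.full((20, 20), 7.0))
        np.testing.assert_array_equal(fd, 2.0)

    def test_noise_rougher_than_gradient(self, rng):
        noise = rng.random((40, 40))
        grad = np.add.outer(np.arange(40.0), np.arange(40.0)) / 80.0
        assert ptpsa_map(noise).mean() > ptpsa_map(grad).mean()

    def test_center_pixel_matches_brute_force_oracle(self, rng):
        img = rng.random((9, 9)) * 10
        # window of the center pixel of a reflect-padded 9x9 image is the image
        fd_map = ptpsa_map(img, window=9)
        assert fd_map[4, 4] == pytest.approx(brute_force_ptpsa_fd(img), abs=1e-10)

    def test_cell_areas_reduce_to_planar_area_on_flat_input(self):
        # each s x s cell of a flat surface has prism area s^2 exactly
        flat = np.full((9, 9), 4.2)
        for s in (1, 2, 4):
            np.testing.assert_allclose(_prism_cell_areas(flat, s), float(s * s))

    def test_range_clamped(self, rng):
        fd = ptpsa_map(rng.random((30, 30)) * 100)
        assert fd.min() >= 2.0 and fd.max() <= 3.0

    def test_invalid_parameters(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            ptpsa_map(img, window=8)
        with pytest.raises(ValueError):
            ptpsa_map(img, scales=(1, 2))
        with pytest.raises(ValueError):
            ptpsa_map(np.zeros((5, 5)), window=9)

    def test_translation_equivariance_interior(self, rng):
        img = rng.random((40, 40))
        a = ptpsa_map(img)
        b = ptpsa_map(np.roll(img, 3, axis=0))
        np.testing.assert_allclose(a[10:25, 10:25], b[13:28, 10:25], atol=1e-12)


from tests._oracles import spectral_fbm2d  # noqa: E402


class TestHurst:
    @pytest.mark.parametrize("h_true", [0.3, 0.5, 0.7])
    def test_recovery_within_tenth(self, h_true):
        ests = []
        for rep in range(50):
            rng = np.random.default_rng(1000 * rep + int(h_true * 10))
            field = spectral_fbm2d(h_true, 128, rng)
            m = mbm_hurst_map(field)
            ests.append(float(m.values[10:-10, 10:-10].mean()))
        assert abs(np.mean(ests) - h_true) <= 0.1

    def test_ordering(self):
        rng = np.random.default_rng(0)
        lo = mbm_hurst_map(spectral_fbm2d(0.3, 128, rng)).values.mean()
        hi = mbm_hurst_map(spectral_fbm2d(0.7, 128, rng)).values.mean()
        assert hi > lo

    def test_constant_window_flagged_as_one(self):
        m = mbm_hurst_map(np.full((20, 20), 3.0))
        assert isinstance(m, TextureMap)
        np.testing.assert_array_equal(m.values, 1.0)
        assert m.degenerate.all()

    def test_range_clamped(self, rng):
        m = mbm_hurst_map(rng.random((40, 40)))
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0


class TestHolder:
    def test_linear_ramp_alpha_one(self):
        ramp = np.add.outer(np.arange(30.0), np.zeros(30))
        hm = holder_map(ramp)
        np.testing.assert_allclose(hm[6:-6, 6:-6], 1.0, atol=1e-9)

    def test_step_edge_alpha_zero(self):
        step = np.zeros((30, 30))
        step[:, 15:] = 1.0
        assert holder_map(step)[15, 15] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_regression(self, rng):
        img = rng.random((20, 20))
        radii = (1, 2, 3, 4)
        hm = holder_map(img, radii)
        i, j = 10, 10
        osc = []
        for r in radii:
            w = img[i - r : i + r + 1, j - r : j + r + 1]
            osc.append(w.max() - w.min())
        slope = np.polyfit(np.log(radii), np.log(osc), 1)[0]
        assert hm[i, j] == pytest.approx(np.clip(slope, 0, 1), abs=1e-9)

    def test_requires_three_radii(self):
        with pytest.raises(ValueError):
            holder_map(np.zeros((10, 10)), radii=(1, 2))


class TestTexton:
    @pytest.fixture(scope="class")
    def collage(self):
        rng = np.random.default_rng(7)
        smooth = 1.0 + np.add.outer(np.arange(32.0), np.arange(32.0)) / 128.0
        ii, jj = np.indices((32, 32))
        check = ((ii // 2 + jj // 2) % 2) * 4.0  # period-4 checkerboard
        img = np.hstack([smooth, check + rng.normal(0, 0.05, (32, 32))])
        return img

    def test_two_texture_separation(self, collage):
        labels, model = texton_label_map(collage, k=2, seed=17)
        left = labels[8:-8, 8:24].ravel()
        right = labels[8:-8, 40:56].ravel()
        purity_left = max(np.mean(left == 0), np.mean(left == 1))
        purity_right = max(np.mean(right == 0), np.mean(right == 1))
        assert purity_left >= 0.95 and purity_right >= 0.95
        assert np.bincount(left, minlength=2).argmax() != np.bincount(right, minlength=2).argmax()

    def test_histogram_sums_to_one(self, collage):
        labels, _ = texton_label_map(collage, k=4, seed=17)
        region = np.zeros_like(labels, bool)
        region[5:20, 5:50] = True
        hist = texton_histogram(labels, region, 4)
        assert hist.sum() == pytest.approx(1.0)

    def test_deterministic_under_seed(self, collage):
        a, _ = texton_label_map(collage, k=4, seed=17)
        b, _ = texton_label_map(collage, k=4, seed=17)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_distinct_vectors_rejected(self):
        with pytest.raises(ValueError):
            texton_label_map(np.zeros((8, 8)), k=4, seed=0)

    def test_bank_composition(self):
        assert len(default_filter_bank()) == 10  # 2 gaussian + 2 LoG + 6 bars


class TestRegionStats:
    def test_constant_region(self):
        s = map_region_stats(np.full(50, 3.0))
        assert s["variance"] == 0.0
        assert s["entropy"] == 0.0
        assert s["energy"] == 1.0

    def test_single_voxel_flags_higher_moments(self):
        s = map_region_stats(np.array([2.5]))
        assert s["mean"] == 2.5
        assert np.isnan(s["skewness"]) and np.isnan(s["kurtosis"])

    def test_empty_region_all_missing(self):
        s = map_region_stats(np.array([]))
        assert all(np.isnan(v) for v in s.values())

    def test_symmetric_sample_skewness_near_zero(self, rng):
        s = map_region_stats(rng.normal(size=200_000))
        assert abs(s["skewness"]) < 0.05
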