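"""Enhancement operators: clip limit arithmetic, CLAHE, illumination
correction, contrast stretching, and median filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dedscreen import enhancement as enh
from dedscreen.enhancement import (
    ClaheConfig,
    ContrastStretchParams,
    DegenerateImageError,
    IlluminationParams,
    MedianFilterParams,
)


class TestExtractGreen:
    def test_selects_channel_one(self):
        img = np.zeros((3, 4, 3), dtype=np.uint8)
        img[..., 0], img[..., 1], img[..., 2] = 10, 200, 30
        assert (enh.extract_green(img) == 200).all()

    def test_two_pixel_extremes(self):
        img = np.array([[[0, 0, 0], [255, 255, 255]]], dtype=np.uint8)
        assert enh.extract_green(img).tolist() == [[0, 255]]

    def test_rejects_gray_input(self):
        with pytest.raises(ValueError):
            enh.extract_green(np.zeros((4, 4), dtype=np.uint8))

    def test_green_vessel_contrast_beats_red(self, dme_fundus):
        """Michelson vessel/background contrast is at least as strong in the
        green channel as in the red, which is why the pipeline uses green."""
        img, gt = dme_fundus
        bg = ~gt.vessel_mask

        def michelson(channel):
            v = channel[gt.vessel_mask].mean()
            b = channel[bg].mean()
            return abs(b - v) / (b + v)

        assert michelson(img[..., 1].astype(float)) >= michelson(img[..., 0].astype(float))


class TestClipLimit:
    @pytest.mark.parametrize(
        "rows, cols, levels, factor, n_avg, n_cl",
        [
            (64, 64, 256, 4, 16.0, 64.0),
            (8, 8, 64, 1, 1.0, 1.0),
            (100, 50, 256, 2, 19.53125, 39.0625),
        ],
    )
    def test_examples(self, rows, cols, levels, factor, n_avg, n_cl):
        res = enh.clahe_clip_limit(ClaheConfig(rows, cols, levels, factor))
        assert res.n_avg == pytest.approx(n_avg)
        assert res.n_cl == pytest.approx(n_cl)

    @given(k=st.integers(min_value=1, max_value=8),
           rows=st.integers(min_value=2, max_value=32),
           cols=st.integers(min_value=2, max_value=32))
    def test_tile_scaling_is_quadratic(self, k, rows, cols):
        base = enh.clahe_clip_limit(ClaheConfig(rows, cols))
        scaled = enh.clahe_clip_limit(ClaheConfig(k * rows, k * cols))
        assert scaled.n_avg == pytest.approx(k**2 * base.n_avg)

    def test_zero_gray_levels_rejected(self):
        with pytest.raises(ValueError):
            ClaheConfig(gray_levels=0)


class TestClahe:
    def test_output_within_range(self, rng):
        img = rng.integers(0, 256, (40, 56), dtype=np.uint8)
        out = enh.clahe(img, ClaheConfig(8, 8))
        assert out.min() >= 0 and out.max() <= 255
        assert out.shape == img.shape

    def test_tile_lut_monotone(self, rng):
        hist = rng.integers(0, 50, 256)
        lut = enh.clahe_tile_lut(hist, clip_limit=10.0, gray_levels=256)
        assert (np.diff(lut) >= 0).all()

    def test_matches_per_tile_oracle_without_interpolation(self, rng):
        """With blending disabled each tile must reproduce an independent
        clipped-histogram-equalization computed bin by bin."""
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        cfg = ClaheConfig(8, 8, 256, 2.0)
        out = enh.clahe(img, cfg, interpolate=False)
        clip = enh.clahe_clip_limit(cfg).n_cl
        for ti in range(2):
            for tj in range(2):
                tile = img[ti * 8 : (ti + 1) * 8, tj * 8 : (tj + 1) * 8]
                hist = np.bincount(tile.ravel(), minlength=256).astype(float)
                excess = np.clip(hist - clip, 0, None).sum()
                clipped = np.minimum(hist, clip) + excess / 256
                cdf = np.cumsum(clipped) / clipped.sum()
                lut = np.floor(cdf * 255 + 0.5)
                expected = lut[tile]
                assert (out[ti * 8 : (ti + 1) * 8, tj * 8 : (tj + 1) * 8] == expected).all()

    def test_tile_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            enh.clahe(np.zeros((4, 4), dtype=np.uint8), ClaheConfig(16, 16))


class TestIlluminationCorrection:
    def test_uniform_image_is_fixed_point(self):
        img = np.full((20, 20), 128, dtype=np.uint8)
        out = enh.correct_illumination(img, IlluminationParams(desired_mean=128, window_side=5))
        assert (out == img).all()

    def test_pointwise_formula(self):
        # constant local mean 90, desired 128: 100 -> 100 + 128 - 90 = 138
        img = np.full((9, 9), 90, dtype=np.uint8)
        img[4, 4] = 100
        out = enh.correct_illumination(img, IlluminationParams(desired_mean=128, window_side=9))
        mu_l = img.mean()
        assert out[4, 4] == round(100 + 128 - mu_l)

    def test_flattens_linear_ramp(self):
        ramp = np.clip(np.linspace(60, 200, 64), 0, 255)
        img = np.tile(ramp, (64, 1)).astype(np.uint8)
        out = enh.correct_illumination(img, IlluminationParams(desired_mean=128, window_side=15))
        interior = out[16:-16, 16:-16].astype(float)
        # local means should sit near the desired level away from borders
        from scipy.ndimage import uniform_filter

        means = uniform_filter(interior, 15)[7:-7, 7:-7]
        assert np.abs(means - 128).max() <= 2

    def test_preserves_global_mean_with_self_target(self, rng):
        img = rng.integers(60, 200, (48, 48), dtype=np.uint8)
        out = enh.correct_illumination(img, IlluminationParams(window_side=9))
        assert abs(out.mean() - img.mean()) <= 1.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            IlluminationParams(window_side=4)


class TestContrastStretch:
    def test_endpoints_and_midpoint(self):
        img = np.array([[50, 100, 150]], dtype=np.uint8)
        out = enh.stretch_contrast(img)
        assert out.tolist() == [[0, 128, 255]]  # 127.5 rounds half up

    def test_idempotent(self, rng):
        img = rng.integers(30, 220, (20, 20), dtype=np.uint8)
        once = enh.stretch_contrast(img)
        twice = enh.stretch_contrast(once)
        assert (once == twice).all()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            enh.stretch_contrast(np.full((5, 5), 77, dtype=np.uint8))

    @given(arrays(np.uint8, (6, 6), elements=st.integers(0, 255)))
    @settings(max_examples=50, deadline=None)
    def test_monotone_affine_map(self, img):
        if img.max() == img.min():
            return
        out = enh.stretch_contrast(img).astype(int)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()
        assert flat_out[flat_in.argmin()] == 0
        assert flat_out[flat_in.argmax()] == 255


class TestMedianFilter:
    def test_center_of_known_window(self):
        img = np.array([[1, 2, 3], [4, 100, 6], [7, 8, 9]], dtype=np.uint8)
        out = enh.median_filter(img)
        assert out[1, 1] == 6

    def test_constant_unchanged(self):
        img = np.full((7, 9), 42, dtype=np.uint8)
        assert (enh.median_filter(img, MedianFilterParams((3, 3))) == 42).all()

    def test_matches_bruteforce_oracle(self, rng):
        img = rng.integers(0, 256, (21, 21), dtype=np.uint8)
        out = enh.median_filter(img, MedianFilterParams((3, 3)))
        for r in range(1, 20):
            for c in range(1, 20):
                window = np.sort(img[r - 1 : r + 2, c - 1 : c + 2].ravel())
                assert out[r, c] == window[4]

    def test_commutes_with_monotone_relabeling(self, rng):
        img = rng.integers(0, 100, (15, 15), dtype=np.uint8)
        relabel = lambda a: (2 * a.astype(np.int64) + 5).astype(np.uint8)
        a = enh.median_filter(relabel(img))
        b = relabel(enh.median_filter(img))
        assert (a[1:-1, 1:-1] == b[1:-1, 1:-1]).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            MedianFilterParams((2, 3))
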