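"""Segmentation: threshold selection oracles, circle voting, and the three
ROI pipelines scored against generator ground truth."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import circle_perimeter

from dedscreen import segmentation as seg
from dedscreen.enhancement import DegenerateImageError
from dedscreen.morphology import StructuringElement
from dedscreen.segmentation import CircleHypothesis, DetectionFailureError, Histogram
from dedscreen.synthetic_fundus import SynthConfig, generate_fundus


def random_histogram(rng: np.random.Generator) -> Histogram:
    counts = np.zeros(256, dtype=np.int64)
    n_modes = rng.integers(2, 5)
    for _ in range(n_modes):
        center = rng.integers(10, 246)
        width = rng.integers(3, 30)
        mass = rng.integers(50, 2000)
        levels = np.clip(rng.normal(center, width, mass).astype(int), 0, 255)
        counts += np.bincount(levels, minlength=256)
    return Histogram(counts, 256)


class TestOtsu:
    def test_two_spikes_separated(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = counts[255] = 500
        stats = seg.otsu_threshold(Histogram(counts, 256))
        bcv = [seg.otsu_stats(Histogram(counts, 256), t).between_var for t in range(255)]
        assert stats.threshold == int(np.argmax(bcv))
        assert stats.threshold < 255  # the two masses end up in different classes
        assert stats.m1 == pytest.approx(0.0)
        assert stats.m2 == pytest.approx(255.0)

    def test_matches_exhaustive_argmax_on_random_histograms(self, rng):
        """The returned threshold attains the exhaustive BCV maximum.

        Comparison is on the criterion value: histograms with empty gaps
        between modes have BCV plateaus where many thresholds tie to within
        floating-point noise.
        """
        for _ in range(20):
            hist = random_histogram(rng)
            stats = seg.otsu_threshold(hist)
            bcv = np.array([seg.otsu_stats(hist, t).between_var for t in range(255)])
            assert stats.between_var == pytest.approx(bcv.max(), rel=1e-9)

    def test_variance_decomposition_identity(self, rng):
        """sigma_w^2(t) + sigma_B^2(t) = sigma^2 at every threshold."""
        hist = random_histogram(rng)
        for t in range(0, 255, 8):
            st = seg.otsu_stats(hist, t)
            assert st.within_var + st.between_var == pytest.approx(st.total_var, abs=1e-9)

    def test_probabilities_and_weights_normalize(self, rng):
        hist = random_histogram(rng)
        assert hist.p.sum() == pytest.approx(1.0)
        st = seg.otsu_stats(hist, 100)
        assert st.w1 + st.w2 == pytest.approx(1.0)

    def test_bcv_max_equals_wcv_min(self, rng):
        """Maximizing between-class variance is exactly minimizing
        within-class variance (they sum to the fixed total variance)."""
        hist = random_histogram(rng)
        stats_list = [seg.otsu_stats(hist, t) for t in range(255)]
        valid = [s for s in stats_list if 0 < s.w1 < 1]
        by_bcv = max(valid, key=lambda s: s.between_var)
        by_wcv = min(valid, key=lambda s: s.within_var)
        assert by_bcv.between_var == pytest.approx(
            hist.p @ np.arange(256) ** 2 - by_bcv.global_mean**2 - by_wcv.within_var,
            rel=1e-9,
        )
        assert abs(by_bcv.within_var - by_wcv.within_var) < 1e-9

    def test_single_bin_rejected(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[7] = 100
        with pytest.raises(DegenerateImageError):
            seg.otsu_threshold(Histogram(counts, 256))


class TestIsodata:
    def test_two_spike_fixed_point(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[10], counts[200] = 100, 100
        assert seg.isodata_threshold(Histogram(counts, 256)) == pytest.approx(105.0)

    def test_symmetric_extremes(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = counts[255] = 50
        assert seg.isodata_threshold(Histogram(counts, 256)) == pytest.approx(127.5)

    def test_gaussian_mixture_matches_fixedpoint_oracle(self, rng):
        lo = np.clip(rng.normal(60, 8, 4000).astype(int), 0, 255)
        hi = np.clip(rng.normal(180, 10, 6000).astype(int), 0, 255)
        img = np.concatenate([lo, hi]).reshape(100, 100).astype(np.uint8)
        t = seg.isodata_threshold(img, tolerance=0.1)
        # independent oracle: iterate the intermeans update to convergence
        vals = img.astype(float).ravel()
        t_o = vals.mean()
        for _ in range(200):
            t_new = (vals[vals <= t_o].mean() + vals[vals > t_o].mean()) / 2
            if abs(t_new - t_o) < 1e-6:
                break
            t_o = t_new
        assert t == pytest.approx(t_o, abs=1.0)

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.filters import threshold_isodata

        img = np.concatenate([
            np.clip(rng.normal(70, 10, 5000), 0, 255),
            np.clip(rng.normal(190, 12, 5000), 0, 255),
        ]).astype(np.uint8).reshape(100, 100)
        assert seg.isodata_threshold(img) == pytest.approx(threshold_isodata(img), abs=1.5)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            seg.isodata_threshold(np.full((8, 8), 9, dtype=np.uint8))


class TestHoughCircles:
    def test_recovers_single_circle(self):
        edges = np.zeros((128, 128), dtype=bool)
        rr, cc = circle_perimeter(60, 50, 20)
        edges[rr, cc] = True
        (top,) = seg.hough_circles(edges, (15, 25), n_best=1)
        assert np.hypot(top.b - 60, top.a - 50) <= 2
        assert abs(top.c - 20) <= 1
        # a perfect circle's vote count equals its edge pixel count
        assert top.votes == len(rr)

    def test_empty_edge_map(self):
        assert seg.hough_circles(np.zeros((32, 32), dtype=bool), (3, 8)) == []

    def test_two_disjoint_circles(self):
        edges = np.zeros((128, 128), dtype=bool)
        for (r, c, rad) in [(40, 40, 15), (90, 95, 22)]:
            rr, cc = circle_perimeter(r, c, rad)
            edges[rr, cc] = True
        hyps = seg.hough_circles(edges, (12, 25), n_best=2)
        assert len(hyps) == 2
        found = sorted((h.b, h.a, h.c) for h in hyps)
        for (fb, fa, fc), (tb, ta, tc) in zip(found, [(40, 40, 15), (90, 95, 22)]):
            assert np.hypot(fb - tb, fa - ta) <= 2 and abs(fc - tc) <= 1

    def test_empty_radius_range_rejected(self):
        with pytest.raises(ValueError):
            seg.hough_circles(np.ones((16, 16), dtype=bool), (10, 5))


class TestRemoveRegion:
    def test_empty_mask_is_identity(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        mask = np.zeros_like(img, dtype=bool)
        assert (seg.remove_region(img, mask) == img).all()

    def test_background_mean_fill(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        mask = np.zeros_like(img, dtype=bool)
        mask[3:6, 3:6] = True
        out = seg.remove_region(img, mask, fill="background-mean")
        expected = round(img[~mask].mean())
        assert (out[mask] == expected).all()
        assert (out[~mask] == img[~mask]).all()

    def test_neighborhood_mean_preserves_unmasked(self, rng):
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        mask = np.zeros_like(img, dtype=bool)
        mask[5:14, 5:14] = True
        out = seg.remove_region(img, mask, fill="neighborhood-mean")
        assert (out[~mask] == img[~mask]).all()
        assert out.shape == img.shape

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.remove_region(np.zeros((4, 4), dtype=np.uint8),
                              np.zeros((5, 5), dtype=bool))


class TestVesselSegmentation:
    def test_recovers_vessel_tree(self, dme_fundus):
        img, gt = dme_fundus
        mask = seg.segment_vessels(img)
        dice = 2 * (mask & gt.vessel_mask).sum() / (mask.sum() + gt.vessel_mask.sum())
        assert dice >= 0.6
        assert mask.dtype == bool and mask.shape == img.shape[:2]

    def test_vessel_free_image_nearly_empty(self):
        rng = np.random.default_rng(3)
        img = np.clip(rng.normal(0, 2, (128, 128, 3))
                      + np.array([190.0, 140.0, 70.0]), 0, 255).astype(np.uint8)
        mask = seg.segment_vessels(img)
        assert mask.mean() < 0.02

    def test_deterministic(self, dme_fundus):
        img, _ = dme_fundus
        assert (seg.segment_vessels(img) == seg.segment_vessels(img)).all()


class TestOpticDisc:
    def test_locates_disc(self, dme_fundus):
        img, gt = dme_fundus
        hyp, mask = seg.detect_optic_disc(img)
        assert np.hypot(hyp.b - gt.disc_center[0], hyp.a - gt.disc_center[1]) <= 5
        assert abs(hyp.c - gt.disc_radius) <= 0.1 * gt.disc_radius + 1e-9

    def test_disc_mask_covers_ground_truth(self, dme_fundus):
        from skimage.draw import disk as draw_disk

        img, gt = dme_fundus
        _, mask = seg.detect_optic_disc(img)
        truth = np.zeros(mask.shape, dtype=bool)
        rr, cc = draw_disk(gt.disc_center, gt.disc_radius + 0.5, shape=mask.shape)
        truth[rr, cc] = True
        assert (mask & truth).sum() / truth.sum() >= 0.9

    def test_no_circle_raises_detection_failure(self):
        rng = np.random.default_rng(5)
        flat = np.clip(rng.normal(120, 2, (128, 128, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(DetectionFailureError):
            seg.detect_optic_disc(flat)


class TestExudates:
    def test_counts_match_ground_truth_blobs(self):
        cfg = SynthConfig(seed=11, exudate_count_range=(3, 3))
        img, gt = generate_fundus(cfg, "mild_dme")
        vessels = seg.segment_vessels(img)
        _, disc = seg.detect_optic_disc(img)
        found = seg.detect_exudates(img, disc, vessels)
        n_found, n_true = ndimage.label(found)[1], ndimage.label(gt.exudate_mask)[1]
        assert n_true == 3 and n_found == 3
        # every detected component overlaps a true blob
        labels, _ = ndimage.label(found)
        for lbl in range(1, n_found + 1):
            assert (gt.exudate_mask & (labels == lbl)).any()

    def test_normal_fundus_nearly_empty(self, normal_fundus):
        img, _ = normal_fundus
        vessels = seg.segment_vessels(img)
        _, disc = seg.detect_optic_disc(img)
        found = seg.detect_exudates(img, disc, vessels)
        assert found.mean() < 0.005

    def test_result_excludes_disc(self, dme_fundus):
        img, _ = dme_fundus
        vessels = seg.segment_vessels(img)
        _, disc = seg.detect_optic_disc(img)
        found = seg.detect_exudates(img, disc, vessels)
        assert not (found & disc).any()

    def test_recall_monotone_in_blob_contrast(self):
        """Detection recall cannot improve as exudate contrast is reduced
        (checked over a three-point contrast ladder)."""
        img, gt = generate_fundus(SynthConfig(seed=21), "mild_dme")
        bg_level = np.median(img[~gt.exudate_mask].reshape(-1, 3), axis=0)
        recalls = []
        for scale in (1.0, 0.45, 0.15):
            faded = img.astype(float).copy()
            faded[gt.exudate_mask] = (
                bg_level + scale * (faded[gt.exudate_mask] - bg_level)
            )
            faded = np.clip(faded, 0, 255).astype(np.uint8)
            vessels = seg.segment_vessels(faded)
            try:
                _, disc = seg.detect_optic_disc(faded)
            except DetectionFailureError:
                disc = np.zeros(faded.shape[:2], dtype=bool)
            found = seg.detect_exudates(faded, disc, vessels)
            tp = (found & gt.exudate_mask).sum()
            recalls.append(tp / max(gt.exudate_mask.sum(), 1))
        assert recalls[0] >= recalls[1] >= recalls[2]
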