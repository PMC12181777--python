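"""Inverse analysis: grayscale, equalization, segmentation, intensity, kinetics."""

import numpy as np
import pytest

from beadsim import synth
from beadsim.analysis import (
    AnalysisError,
    BeadMask,
    FormatError,
    MeasurementError,
    SegmentationConfig,
    analyze_timelapse,
    enhance_contrast,
    fit_disintegration,
    measure_intensity,
    segment_bead,
    summarize_screen,
    to_gray,
)
from beadsim.synth import CameraModel, DisintegrationParams, WellScene, render_frame

from conftest import iou


class TestToGray:
    def test_equal_channels_identity(self):
        frame = np.full((4, 4, 3), 137, dtype=np.uint8)
        assert (to_gray(frame) == 137).all()

    def test_all_zero(self):
        assert (to_gray(np.zeros((4, 4, 3), dtype=np.uint8)) == 0).all()

    def test_hand_computed_weighting(self):
        frame = np.array(
            [[[255, 0, 0], [0, 255, 0]],
             [[0, 0, 255], [100, 50, 200]]], dtype=np.uint8)
        # round(0.299 R + 0.587 G + 0.114 B)
        expected = np.array([[76, 150], [29, 82]], dtype=np.uint8)
        assert np.array_equal(to_gray(frame), expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(FormatError):
            to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestEnhanceContrast:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 42, dtype=np.uint8)
        assert np.array_equal(enhance_contrast(img), img)

    def test_two_level_mapping_by_hand(self):
        # 25 % at level 10, 75 % at level 20; out(v) = round(255 (cdf - cdf_min)/(N - cdf_min))
        img = np.full((4, 4), 20, dtype=np.uint8)
        img[0, :] = 10  # 4 of 16 pixels
        out = enhance_contrast(img)
        assert set(np.unique(out)) == {0, 255}
        assert (out[img == 10] == 0).all()
        assert (out[img == 20] == 255).all()

    def test_rank_order_preserved_and_range_grows(self):
        rng = np.random.default_rng(0)
        img = rng.integers(100, 140, size=(32, 32)).astype(np.uint8)
        out = enhance_contrast(img)
        # order of distinct values preserved
        for a in np.unique(img):
            for b in np.unique(img):
                if a < b:
                    assert out[img == a][0] <= out[img == b][0]
        assert int(out.max()) - int(out.min()) >= int(img.max()) - int(img.min())

    def test_low_contrast_bead_separation_after_equalization(self):
        img = np.full((64, 64), 8, dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2] = 20
        out = enhance_contrast(img)
        sep = int(out[img == 20][0]) - int(out[img == 8][0])
        assert sep >= 64


class TestSegmentBead:
    def test_clean_disk_mask_matches_truth(self, clean_camera):
        scene = WellScene(opacity=0.8, background_level=0)
        frame = render_frame(scene, clean_camera)
        mask = segment_bead(frame)
        assert mask.found
        assert iou(mask.mask, synth.true_bead_mask(scene, clean_camera)) >= 0.98

    def test_blank_frame_not_found(self):
        frame = render_frame(WellScene(bead_present=False),
                             CameraModel(noise_sigma=4, seed=2))
        assert not segment_bead(frame).found

    def test_equalization_required_for_faint_bead(self):
        frame = render_frame(WellScene(opacity=0.1, background_level=6),
                             CameraModel(noise_sigma=4, seed=7))
        assert not segment_bead(frame, SegmentationConfig(equalize="never")).found
        assert segment_bead(frame, SegmentationConfig(equalize="auto")).found

    def test_center_bias_selects_central_component(self, clean_camera):
        scene = WellScene(opacity=0.9, radius=60, background_level=0)
        frame = render_frame(scene, clean_camera).copy()
        frame[5:40, 5:120] = 230  # bright corner artifact, bigger than the bead
        mask = segment_bead(frame, SegmentationConfig(center_bias=True))
        cx, cy = mask.centroid
        assert abs(cx - 320) < 5 and abs(cy - 240) < 5

    def test_mask_found_false_implies_zero_area(self):
        empty = BeadMask.empty((10, 10))
        assert not empty.found and empty.area == 0

    def test_oracle_equivalence_on_tiny_frames(self):
        """Fixed-threshold segmentation equals a brute-force flood-fill reference."""

        def reference(gray, thr, min_area):
            h, w = gray.shape
            above = gray > thr
            seen = np.zeros_like(above, dtype=bool)
            comps = []
            for sy in range(h):
                for sx in range(w):
                    if above[sy, sx] and not seen[sy, sx]:
                        stack, comp = [(sy, sx)], []
                        seen[sy, sx] = True
                        while stack:
                            y, x = stack.pop()
                            comp.append((y, x))
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    ny, nx = y + dy, x + dx
                                    if (0 <= ny < h and 0 <= nx < w
                                            and above[ny, nx] and not seen[ny, nx]):
                                        seen[ny, nx] = True
                                        stack.append((ny, nx))
                        if len(comp) >= min_area:
                            comps.append(comp)
            if not comps:
                return None
            cy0, cx0 = (h - 1) / 2, (w - 1) / 2
            def center_dist(comp):
                ys, xs = zip(*comp)
                return (np.mean(ys) - cy0) ** 2 + (np.mean(xs) - cx0) ** 2
            best = min(comps, key=center_dist)
            mask = np.zeros_like(above, dtype=bool)
            for y, x in best:
                mask[y, x] = True
            return mask

        rng = np.random.default_rng(21)
        cfg_base = dict(equalize="never", contrast_trigger=0.0,
                        threshold_method="fixed", morph_radius=0)
        for trial in range(20):
            gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            frame = np.repeat(gray[:, :, None], 3, axis=2)
            thr = int(rng.integers(40, 220))
            min_area = int(rng.integers(1, 6))
            cfg = SegmentationConfig(fixed_threshold=thr, min_area=min_area, **cfg_base)
            got = segment_bead(frame, cfg)
            want = reference(gray, thr, min_area)
            if want is None:
                assert not got.found, f"trial {trial}"
            else:
                assert got.found and np.array_equal(got.mask, want), f"trial {trial}"


class TestMeasureIntensity:
    def test_uniform_disk_exact_statistics(self, clean_camera):
        scene = WellScene(opacity=100 / 255, background_level=0)
        frame = render_frame(scene, clean_camera)
        truth = synth.true_bead_mask(scene, clean_camera)
        mask = BeadMask(truth, True, int(truth.sum()), None)
        res = measure_intensity(frame, mask)
        assert res.mean == pytest.approx(100.0)
        assert res.sd == 0.0
        assert res.n_pixels == truth.sum()

    def test_noisy_disk_mean_within_sampling_error(self):
        cam = CameraModel(noise_sigma=5.0, blur_radius=0, seed=31)
        scene = WellScene(opacity=200 / 255, background_level=0)
        frame = render_frame(scene, cam)
        truth = synth.true_bead_mask(scene, cam)
        mask = BeadMask(truth, True, int(truth.sum()), None)
        res = measure_intensity(frame, mask)
        assert abs(res.mean - 200.0) <= 3 * 5 / np.sqrt(res.n_pixels) + 0.5

    def test_not_found_mask_is_error(self, clean_camera):
        frame = render_frame(WellScene(), clean_camera)
        with pytest.raises(MeasurementError):
            measure_intensity(frame, BeadMask.empty(frame.shape[:2]))

    def test_intensity_invariant_to_equalize_setting_when_mask_identical(self):
        frame = render_frame(WellScene(opacity=0.7, background_level=0),
                             CameraModel(noise_sigma=2, seed=4))
        m_never = segment_bead(frame, SegmentationConfig(equalize="never"))
        m_always = segment_bead(frame, SegmentationConfig(equalize="always"))
        if np.array_equal(m_never.mask, m_always.mask):
            a = measure_intensity(frame, m_never)
            b = measure_intensity(frame, m_always)
            assert a == b


class TestScreenSummary:
    def test_single_condition_single_row(self, clean_camera):
        recs = synth.simulate_screen([1.5], [1.0], cam=clean_camera)
        table = summarize_screen(recs)
        assert len(table) == 1
        assert bool(table.iloc[0]["found"])

    def test_per_row_unimodal_with_interior_maximum(self):
        recs = synth.simulate_screen(cam=CameraModel(seed=8, noise_sigma=2))
        table = summarize_screen(recs)
        for alg, row in table.groupby("alginate_pct"):
            row = row.sort_values("cacl2_pct")
            found = row[row["found"]]
            peak_ca = found.loc[found["mean"].idxmax(), "cacl2_pct"]
            assert row["cacl2_pct"].iloc[0] < peak_ca < row["cacl2_pct"].iloc[-1]

    def test_lowest_cacl2_column_is_faintest_or_missing(self):
        recs = synth.simulate_screen(cam=CameraModel(seed=8, noise_sigma=2))
        table = summarize_screen(recs)
        for alg, row in table.groupby("alginate_pct"):
            first = row[row["cacl2_pct"] == 0.1].iloc[0]
            rest = row[(row["cacl2_pct"] > 0.1) & row["found"]]
            assert (not first["found"]) or (first["mean"] <= rest["mean"].min())


class TestKinetics:
    SCHEDULE = list(np.linspace(0, 900, 20))

    def test_parameter_recovery(self):
        d = DisintegrationParams(t_edta=300.0, k_decay=0.01)
        recs = synth.simulate_timelapse(d, self.SCHEDULE,
                                        CameraModel(seed=13, noise_sigma=3))
        series, fit = analyze_timelapse(recs)
        interval = self.SCHEDULE[1] - self.SCHEDULE[0]
        assert fit.onset_found
        assert abs(fit.onset_t - 300.0) <= interval
        assert abs(fit.k_decay_hat / 0.01 - 1) <= 0.05

    def test_no_edta_no_onset(self):
        recs = synth.simulate_timelapse(DisintegrationParams(t_edta=None),
                                        self.SCHEDULE, CameraModel(seed=14, noise_sigma=3))
        _, fit = analyze_timelapse(recs)
        assert not fit.onset_found

    def test_noise_free_series_reproduces_time_course(self, clean_camera):
        d = DisintegrationParams(t_edta=300.0)
        recs = synth.simulate_timelapse(
            d, self.SCHEDULE, clean_camera,
            scene_template=WellScene(background_level=0))
        series, _ = analyze_timelapse(recs)
        t, y = series.found_points()
        for tt, yy in zip(t, y):
            assert yy == pytest.approx(round(synth.opacity_time_course(d, tt) * 255))

    def test_too_few_points_is_error(self):
        with pytest.raises(AnalysisError):
            fit_disintegration(np.array([0.0, 1, 2]), np.array([5.0, 4, 3]))

    def test_all_blank_series_is_error(self):
        cam = CameraModel(noise_sigma=2, seed=3)
        recs = synth.simulate_timelapse(
            DisintegrationParams(), self.SCHEDULE, cam,
            scene_template=WellScene(bead_present=False))
        with pytest.raises(AnalysisError):
            analyze_timelapse(recs)


class TestForwardInverseConsistency:
    def test_opacity_ladder_recovered_exactly(self, clean_camera):
        for opacity in np.arange(0.1, 1.001, 0.1):
            scene = WellScene(opacity=float(opacity), background_level=0)
            frame = render_frame(scene, clean_camera)
            mask = segment_bead(frame)
            res = measure_intensity(frame, mask)
            assert res.mean == pytest.approx(round(opacity * 255))

    def test_monotone_recovery_across_ladder(self):
        cam = CameraModel(noise_sigma=3, seed=17)
        means = []
        for opacity in np.linspace(0.2, 1.0, 9):
            frame = render_frame(WellScene(opacity=float(opacity), background_level=0), cam)
            mask = segment_bead(frame)
            means.append(measure_intensity(frame, mask).mean)
        assert all(b > a - 1.0 for a, b in zip(means, means[1:]))
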