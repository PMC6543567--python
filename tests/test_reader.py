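"""The image pipeline: ROI, pad detection, sampling, frame averaging."""
import numpy as np
import pytest

import uristrip as u
from uristrip import (
    HueWrapError,
    InsufficientFramesError,
    PadNotFoundError,
    RoiBoundsError,
    SamplingError,
)
from uristrip.geometry import Rect
from uristrip.reader import PadDetection, sample_center_hues


def _hsv_roi_with_pads(shape, pads, pad_hue=100.0, pad_sat=0.7):
    """Directly build an HSV ROI: zero-saturation background, saturated pads."""
    hsv = np.zeros(shape + (3,), dtype=float)
    hsv[..., 2] = 0.9
    for rect in pads:
        hsv[rect.slices] = (pad_hue, pad_sat, 0.7)
    return hsv


class TestExtractRoi:
    def test_full_frame_guide_is_identity(self):
        frame = np.random.default_rng(0).random((30, 40, 3))
        assert np.array_equal(u.extract_roi(frame, Rect(0, 0, 40, 30)), frame)

    def test_crop_equals_source_subrect(self):
        frame = np.random.default_rng(1).random((80, 80, 3))
        roi = u.extract_roi(frame, Rect(10, 10, 50, 50))
        assert roi.shape == (50, 50, 3)
        assert np.array_equal(roi, frame[10:60, 10:60])

    def test_overhanging_guide_rejected(self):
        frame = np.zeros((30, 30, 3))
        with pytest.raises(RoiBoundsError):
            u.extract_roi(frame, Rect(20, 20, 20, 20))


class TestDetectPad:
    def test_bbox_matches_ground_truth_noiseless(self, config):
        spec = u.default_strip_spec(125.0)
        img, truth = u.render_strip_frame(spec, seed=0)
        guide = u.protein_pad_guide(spec)
        pad = u.detect_pad(u.rgb_to_hsv(u.extract_roi(img, guide)), config)
        det = pad.bbox.shifted(guide.x, guide.y)
        for got, want in (
            (det.x, truth.pad_bbox.x), (det.y, truth.pad_bbox.y),
            (det.x1, truth.pad_bbox.x1), (det.y1, truth.pad_bbox.y1),
        ):
            assert abs(got - want) <= 2

    def test_bbox_matches_ground_truth_under_noise(self, config):
        spec = u.default_strip_spec(125.0, noise_sd=0.02)
        img, truth = u.render_strip_frame(spec, seed=7)
        guide = u.protein_pad_guide(spec)
        pad = u.detect_pad(u.rgb_to_hsv(u.extract_roi(img, guide)), config)
        det = pad.bbox.shifted(guide.x, guide.y)
        assert abs(det.x - truth.pad_bbox.x) <= 2
        assert abs(det.y - truth.pad_bbox.y) <= 2
        assert abs(det.x1 - truth.pad_bbox.x1) <= 2
        assert abs(det.y1 - truth.pad_bbox.y1) <= 2

    def test_uniform_roi_has_no_pad(self, config):
        hsv = np.zeros((60, 60, 3))
        hsv[..., 2] = 0.8
        with pytest.raises(PadNotFoundError):
            u.detect_pad(hsv, config)

    def test_two_equal_pads_tie_break_to_roi_center(self, config):
        near = Rect(40, 40, 20, 20)   # centered in the 100x100 ROI
        far = Rect(5, 5, 20, 20)
        hsv = _hsv_roi_with_pads((100, 100), [far, near])
        pad = u.detect_pad(hsv, config)
        assert abs(pad.bbox.x - near.x) <= 2 and abs(pad.bbox.y - near.y) <= 2

    def test_center_region_is_inner_half_of_bbox(self, config):
        hsv = _hsv_roi_with_pads((80, 80), [Rect(20, 20, 40, 40)])
        pad = u.detect_pad(hsv, config)
        assert pad.bbox.contains(pad.center)
        assert pad.center.w == pad.bbox.w // 2
        assert pad.center.h == pad.bbox.h // 2


class TestSampleCenterHues:
    def _pad(self, center):
        return PadDetection(bbox=center.expanded(center.w), mask=None, center=center)

    def test_uniform_pad_mean_is_exact_for_any_seed(self):
        hsv = _hsv_roi_with_pads((60, 60), [Rect(10, 10, 40, 40)])
        pad = self._pad(Rect(20, 20, 20, 20))
        for seed in (0, 1, 99):
            assert sample_center_hues(hsv, pad, 64, seed) == pytest.approx(100.0)

    def test_same_seed_same_mean(self):
        rng = np.random.default_rng(0)
        hsv = np.zeros((40, 40, 3))
        hsv[..., 0] = 80.0 + 40.0 * rng.random((40, 40))
        hsv[..., 1] = 0.7
        pad = self._pad(Rect(5, 5, 30, 30))
        a = sample_center_hues(hsv, pad, 64, 123)
        b = sample_center_hues(hsv, pad, 64, 123)
        assert a == b
        assert a != sample_center_hues(hsv, pad, 64, 124)

    def test_expected_sampled_mean_matches_brute_force_center_mean(self):
        """Averaged over many seeds, 64-point random sampling agrees with
        the exhaustive mean over all center-region pixels (the oracle)."""
        ys, xs = np.mgrid[0:40, 0:40]
        hsv = np.zeros((40, 40, 3))
        hsv[..., 0] = 80.0 + xs * 1.5  # linear hue gradient 80..138.5
        hsv[..., 1] = 0.7
        center = Rect(5, 5, 30, 30)
        pad = self._pad(center)
        oracle = hsv[center.slices][..., 0].mean()
        means = [sample_center_hues(hsv, pad, 64, seed) for seed in range(1000)]
        assert np.mean(means) == pytest.approx(oracle, abs=0.5)

    def test_center_too_small_for_sample_count(self):
        hsv = _hsv_roi_with_pads((30, 30), [Rect(5, 5, 20, 20)])
        pad = self._pad(Rect(10, 10, 7, 7))  # 49 px < 64 samples
        with pytest.raises(SamplingError):
            sample_center_hues(hsv, pad, 64, 0)

    def test_wrap_adjacent_hues_rejected(self):
        hsv = _hsv_roi_with_pads((60, 60), [Rect(10, 10, 40, 40)], pad_hue=10.0)
        pad = self._pad(Rect(20, 20, 20, 20))
        with pytest.raises(HueWrapError):
            sample_center_hues(hsv, pad, 64, 0)


class TestEstimateHue:
    def test_noiseless_sequence_recovers_hue_exactly(self, unit_calibration):
        spec = u.default_strip_spec(100.0, compact=True)
        frames = u.render_sequence(spec, 30, seed=0)
        est = u.estimate_hue(
            frames, u.protein_pad_guide(spec, 24), unit_calibration, u.AnalysisConfig(seed=1)
        )
        assert est.grand_mean_deg == pytest.approx(100.0, abs=1e-6)
        assert est.n_frames == 30 and est.n_samples == 64
        assert est.grand_mean_deg == pytest.approx(np.mean(est.per_frame_means_deg))

    def test_too_few_frames(self, unit_calibration, config):
        spec = u.default_strip_spec(100.0, compact=True)
        frames = u.render_sequence(spec, 29, seed=0)
        with pytest.raises(InsufficientFramesError):
            u.estimate_hue(frames, u.protein_pad_guide(spec, 24), unit_calibration, config)

    def test_noisy_sequence_lands_within_a_degree(self, unit_calibration):
        spec = u.default_strip_spec(100.0, noise_sd=0.02, compact=True)
        guide = u.protein_pad_guide(spec, 24)
        for run in range(5):
            frames = u.render_sequence(spec, 30, seed=run)
            est = u.estimate_hue(frames, guide, unit_calibration, u.AnalysisConfig(seed=run))
            assert est.grand_mean_deg == pytest.approx(100.0, abs=1.0)

    def test_identical_inputs_identical_estimate(self, unit_calibration):
        spec = u.default_strip_spec(100.0, noise_sd=0.02, compact=True)
        frames = u.render_sequence(spec, 30, seed=2)
        guide = u.protein_pad_guide(spec, 24)
        cfg = u.AnalysisConfig(seed=9)
        a = u.estimate_hue(frames, guide, unit_calibration, cfg)
        b = u.estimate_hue(frames, guide, unit_calibration, cfg)
        assert a == b


class TestReadStrip:
    def test_noiseless_mid_band_hue_reads_high(self, unit_calibration, fixture_edges, config):
        spec = u.default_strip_spec(125.0, compact=True)  # middle of the 2+ band
        frames = u.render_sequence(spec, 30, seed=0)
        result = u.read_strip(
            frames, u.protein_pad_guide(spec, 24), unit_calibration, fixture_edges, config
        )
        assert result.level == u.ProteinLevel.PLUS_2
        assert result.category == u.ProteinCategory.HIGH
        assert result.calibration_passed

    def test_no_strip_sequence_raises_naming_the_frame(
        self, unit_calibration, fixture_edges, config
    ):
        frames = [np.full((100, 100, 3), 0.5)] * 30
        with pytest.raises(PadNotFoundError, match="frame 0"):
            u.read_strip(frames, Rect(0, 0, 100, 100), unit_calibration, fixture_edges, config)

    def test_level_and_category_consistent_with_binning(
        self, unit_calibration, fixture_edges, config
    ):
        for level in u.ProteinLevel:
            spec = u.spec_for_level(level, compact=True)
            frames = u.render_sequence(spec, 30, seed=0)
            result = u.read_strip(
                frames, u.protein_pad_guide(spec, 24), unit_calibration, fixture_edges, config
            )
            assert u.bin_hue(result.hue.grand_mean_deg, fixture_edges) == (
                result.level, result.category,
            )
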