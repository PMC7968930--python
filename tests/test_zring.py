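"""Kymographs, background correction, ring detection, FWHM, spore stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sephkit import synth, zring

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian_profile(n, center, sigma, amplitude, baseline=0.0):
    x = np.arange(n, dtype=float)
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestBuildKymograph:
    def test_uniform_frame_gives_constant_row(self):
        stack = np.full((4, 30, 50), 7.5)
        kymo = zring.build_kymograph(stack, [(5, 15), (45, 15)])
        assert np.allclose(kymo.matrix, 7.5)

    def test_horizontal_polyline_matches_row_averaging_oracle(self, rng):
        # axis-aligned reslice must equal direct row slicing + averaging
        stack = rng.uniform(0, 100, size=(6, 21, 40))
        row, width = 10, 5
        kymo = zring.build_kymograph(stack, [(3, row), (36, row)],
                                     line_width=width)
        oracle = stack[:, row - 2:row + 3, 3:37].mean(axis=1)
        assert np.allclose(kymo.matrix, oracle)

    def test_vertical_polyline_matches_column_averaging_oracle(self, rng):
        stack = rng.uniform(0, 100, size=(3, 40, 21))
        col = 10
        kymo = zring.build_kymograph(stack, [(col, 3), (col, 36)],
                                     line_width=5)
        oracle = stack[:, 3:37, col - 2:col + 3].mean(axis=2)
        assert np.allclose(kymo.matrix, oracle)

    def test_24_frames_at_10_min_span_240_min(self):
        stack = np.zeros((24, 11, 30))
        kymo = zring.build_kymograph(stack, [(2, 5), (27, 5)],
                                     frame_interval=10.0)
        assert kymo.duration == pytest.approx(240.0)
        assert kymo.times[-1] == pytest.approx(230.0)

    def test_out_of_bounds_and_degenerate_polylines_rejected(self):
        stack = np.zeros((2, 10, 10))
        with pytest.raises(ValueError):
            zring.build_kymograph(stack, [(0, 1), (9, 1)], line_width=5)
        with pytest.raises(ValueError):
            zring.build_kymograph(stack, [(4, 4), (4, 4)])
        with pytest.raises(ValueError):
            zring.build_kymograph(stack, [(4, 4)])


class TestBackgroundCorrect:
    @staticmethod
    def between_class_variance(values, t):
        lo, hi = values[values < t], values[values >= t]
        if lo.size == 0 or hi.size == 0:
            return -np.inf
        return lo.size * hi.size * (lo.mean() - hi.mean()) ** 2

    def test_two_level_image_matches_exhaustive_oracle(self, rng):
        # 90% background at 10, 10% signal at 200: the low class must be
        # zeroed, the high class uniformly shifted by a threshold that
        # attains the exhaustive between-class-variance maximum
        values = np.where(rng.uniform(size=(5, 40, 40)) < 0.9, 10.0, 200.0)
        corrected = zring.background_correct(values, n_classes=2)
        assert np.all(corrected[values == 10.0] == 0.0)
        high = corrected[values == 200.0]
        t_impl = 200.0 - high[0]
        assert np.all(high == high[0])
        assert 10.0 < t_impl <= 200.0
        flat = values.ravel()
        v_impl = self.between_class_variance(flat, t_impl)
        v_max = max(self.between_class_variance(flat, t)
                    for t in np.linspace(10.0, 200.0, 573)[1:])
        assert v_impl == pytest.approx(v_max, rel=1e-12)

    def test_pure_background_zeroed(self, rng):
        # dim noise only: everything classed as background goes to 0 and
        # what survives has the threshold removed
        stack = rng.normal(20, 1, size=(3, 32, 32))
        corrected = zring.background_correct(stack)
        assert corrected.min() == 0.0
        assert corrected.max() < stack.max()

    def test_minimum_exactly_zero(self, one_ring_truth):
        stack, _ = synth.gen_timelapse(one_ring_truth, seed=0)
        corrected = zring.background_correct(stack)
        assert corrected.min() == 0.0
        assert np.all(corrected >= 0)

    def test_idempotent(self, one_ring_truth):
        stack, _ = synth.gen_timelapse(one_ring_truth, seed=0)
        once = zring.background_correct(stack)
        twice = zring.background_correct(once)
        assert np.array_equal(once, twice)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            zring.background_correct(np.full((2, 8, 8), 3.0))


class TestRingTraces:
    def test_constant_stack_traces_constant(self):
        stack = np.full((5, 30, 60), 4.0)
        traces = zring.ring_traces(stack, [20.0, 40.0])
        for tr in traces:
            assert np.allclose(tr.values, 4.0)

    def test_single_ring_matches_direct_roi_sum_oracle(self, one_ring_truth):
        profile_stack, _ = synth.gen_timelapse(one_ring_truth, seed=0)
        stack = synth.profile_stack_to_image(profile_stack, width=24)
        cx = one_ring_truth.rings[0].position / one_ring_truth.pixel_size
        (trace,) = zring.ring_traces(stack, [cx], roi_shape=(10, 20))
        x0 = int(round(cx - 5))
        y0 = int(round((24 - 1) / 2 - 10))
        oracle = stack[:, y0:y0 + 20, x0:x0 + 10].sum(axis=(1, 2)) / 200.0
        assert np.allclose(trace.values, oracle)
        # the trace follows the planted lifecycle + background, up to the
        # averaging of the Gaussian over the 10 px ROI span
        ring = one_ring_truth.rings[0]
        amps = ring.amplitude_at(one_ring_truth.times)
        assert np.corrcoef(trace.values, amps)[0, 1] > 0.999

    def test_single_trace_sem_zero_and_flagged(self):
        stack = np.full((4, 30, 30), 2.0)
        traces = zring.ring_traces(stack, [15.0])
        agg = zring.aggregate_trace(traces)
        assert np.all(agg["sem"] == 0.0)
        assert not agg["sem_defined"].any()

    def test_aggregate_mean_and_sem(self):
        stack = np.zeros((3, 30, 60))
        stack[:, :, :30] = 1.0
        stack[:, :, 30:] = 3.0
        traces = zring.ring_traces(stack, [15.0, 45.0])
        agg = zring.aggregate_trace(traces)
        assert np.allclose(agg["mean"], 2.0)
        assert np.allclose(agg["sem"], np.sqrt(2.0) / np.sqrt(2.0))
        assert agg["sem_defined"].all()

    def test_roi_out_of_bounds_rejected(self):
        stack = np.zeros((2, 15, 15))
        with pytest.raises(ValueError):
            zring.ring_traces(stack, [2.0], roi_shape=(10, 20))


class TestDetectRings:
    def test_three_gaussians_detected_at_centers(self):
        profile = (gaussian_profile(300, 50, 4, 500)
                   + gaussian_profile(300, 150, 4, 400)
                   + gaussian_profile(300, 250, 4, 300))
        detections = zring.detect_rings(profile, min_intensity=100,
                                        pixel_size=1.0)
        assert len(detections) == 3
        for det, center in zip(detections, (50, 150, 250)):
            assert abs(det.index - center) <= 1
        # ordered by position with descending planted amplitudes
        amps = [d.amplitude for d in detections]
        assert amps == sorted(amps, reverse=True)

    def test_amplitude_below_100_rejected(self):
        profile = gaussian_profile(100, 50, 3, 90)
        assert zring.detect_rings(profile, min_intensity=100) == []

    def test_monotone_ramp_has_no_peaks(self):
        assert zring.detect_rings(np.linspace(0, 500, 100)) == []

    def test_plateau_resolves_to_center(self):
        profile = np.zeros(21)
        profile[8:13] = 150.0  # 5-sample plateau centred at 10
        (det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=1.0)
        assert det.index == 10
        profile = np.zeros(20)
        profile[8:12] = 150.0  # even plateau: floor of midpoint
        (det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=1.0)
        assert det.index == 9

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            zring.detect_rings(np.array([1.0, 2.0]))


class TestRingWidth:
    @pytest.mark.parametrize("sigma", [1.5, 2.0, 4.0])
    def test_gaussian_closed_form(self, sigma):
        profile = gaussian_profile(200, 100, sigma, 500)
        (det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=1.0)
        det = zring.ring_width(profile, det, pixel_size=1.0)
        assert det.fwhm_ok
        assert det.fwhm == pytest.approx(FWHM_FACTOR * sigma, abs=0.05)

    def test_triangle_exact(self):
        x = np.arange(41, dtype=float)
        profile = np.clip(300.0 * (1 - np.abs(x - 20) / 4.0), 0, None)
        (det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=1.0)
        det = zring.ring_width(profile, det, pixel_size=1.0)
        assert det.fwhm == pytest.approx(4.0)

    def test_recovers_planted_sigma_from_synthetic_stack(self, one_ring_truth):
        stack, _ = synth.gen_timelapse(one_ring_truth, seed=0)
        profile = stack.mean(axis=0)
        (det,) = zring.detect_rings(profile, min_intensity=100,
                                    pixel_size=one_ring_truth.pixel_size)
        det = zring.ring_width(profile, det,
                               pixel_size=one_ring_truth.pixel_size)
        expected = FWHM_FACTOR * one_ring_truth.rings[0].sigma
        assert det.fwhm == pytest.approx(expected, rel=0.05)

    @given(shift=st.floats(-200, 200), scale=st.floats(0.01, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance_and_pixel_scaling(self, shift, scale):
        # baseline subtraction makes FWHM invariant to adding a constant;
        # physical width scales linearly with the pixel size
        profile = gaussian_profile(120, 60, 3, 400)
        (det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=1.0)
        base = zring.ring_width(profile, det, pixel_size=1.0).fwhm
        shifted = zring.ring_width(profile + shift, det, pixel_size=1.0).fwhm
        scaled = zring.ring_width(profile, det, pixel_size=scale).fwhm
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    def test_edge_peak_flagged_undefined(self):
        profile = np.linspace(0, 400, 50)  # maximum at the array edge
        det = zring.RingDetection(index=49, position=49.0, amplitude=400.0,
                                  prominence=400.0)
        det = zring.ring_width(profile, det, pixel_size=1.0)
        assert not det.fwhm_ok
        assert np.isnan(det.fwhm)


class TestSporeStats:
    def test_all_equal_lengths(self):
        df = pd.DataFrame({"replicate": [1, 1, 2, 2, 3, 3],
                           "length_um": [1.5] * 6})
        st_ = zring.spore_stats(df)
        assert st_.grand_mean == 1.5
        assert st_.sd == 0.0
        assert st_.ci95 == (1.5, 1.5)

    def test_replicate_means_1_2_3_t_interval(self):
        df = pd.DataFrame({"replicate": [1, 2, 3],
                           "length_um": [1.0, 2.0, 3.0]})
        st_ = zring.spore_stats(df)
        half = 4.302652729911275 / np.sqrt(3.0)  # t(0.975, df=2) * sd/sqrt(n)
        assert st_.grand_mean == pytest.approx(2.0)
        assert st_.ci95[0] == pytest.approx(2.0 - half)
        assert st_.ci95[1] == pytest.approx(2.0 + half)

    def test_ci_covers_truth_in_at_least_90_of_100_runs(self):
        covered = 0
        for seed in range(100):
            df = synth.gen_spore_lengths(mean=1.3, sd=0.2, n_per_rep=40,
                                         n_reps=3, seed=seed)
            st_ = zring.spore_stats(df)
            covered += st_.ci95[0] <= 1.3 <= st_.ci95[1]
        assert covered >= 90

    def test_single_replicate_ci_flagged(self):
        df = pd.DataFrame({"replicate": [1, 1, 1],
                           "length_um": [1.0, 1.2, 1.4]})
        st_ = zring.spore_stats(df)
        assert not st_.ci_defined
        assert np.isnan(st_.ci95[0])
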