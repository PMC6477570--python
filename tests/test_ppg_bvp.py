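"""Spatial-entropy BVP extraction and PP-interval detection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ppgtherm.errors import (
    ConfigurationError,
    InvalidInputError,
    PipelineStageError,
)
from ppgtherm.ppg_bvp import (
    PpgConfig,
    detect_pp_intervals,
    equalize_amplitude,
    estimate_raw_bvp,
    extract_ppg,
    resample_uniform,
    spatial_entropy,
)
from ppgtherm.signals import BvpSignal, EntropySignal, FrameStack
from ppgtherm.synthetic import RRParams, generate_rr, render_ppg_frames


def brute_force_entropy(frame, nbins=256):
    counts, _ = np.histogram(frame, bins=nbins, range=(0.0, 256.0))
    p = counts / counts.sum()
    return -sum(pi * np.log2(pi) for pi in p if pi > 0)


class TestSpatialEntropy:
    def test_constant_frame_is_zero(self):
        assert spatial_entropy(np.full((8, 8), 117, dtype=np.uint8)) == 0.0

    def test_uniform_histogram_is_eight_bits(self):
        frame = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert spatial_entropy(frame) == pytest.approx(8.0, abs=1e-12)

    def test_hand_enumerated_two_by_two(self):
        # p = (0.5, 0.25, 0.25) -> 1.5 bits
        frame = np.array([[10, 10], [20, 30]], dtype=np.uint8)
        assert spatial_entropy(frame) == pytest.approx(1.5, abs=1e-12)

    def test_empty_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            spatial_entropy(np.empty((0, 0), dtype=np.uint8))

    @given(arrays(np.uint8, (6, 7)), st.sampled_from([2, 16, 256]))
    def test_bounded_and_matches_oracle(self, frame, nbins):
        h = spatial_entropy(frame, nbins)
        assert 0.0 <= h <= np.log2(nbins) + 1e-12
        assert h == pytest.approx(brute_force_entropy(frame, nbins), abs=1e-12)


class TestEstimateRawBvp:
    def test_identical_frames_give_constant_series(self):
        frame = np.arange(64, dtype=np.uint8).reshape(8, 8)
        stack = FrameStack(np.stack([frame] * 5), np.arange(5.0))
        out = estimate_raw_bvp(stack)
        assert np.ptp(out.values) == 0.0

    def test_alternating_frames_alternate_zero_and_minus_eight(self):
        const = np.full((16, 16), 40, dtype=np.uint8)
        uniform = np.arange(256, dtype=np.uint8).reshape(16, 16)
        stack = FrameStack(np.stack([const, uniform] * 3), np.arange(6.0))
        out = estimate_raw_bvp(stack, "entropy")
        np.testing.assert_allclose(out.values, [0.0, -8.0] * 3, atol=1e-12)

    def test_mean_intensity_baseline(self):
        frame = np.array([[10, 30], [20, 40]], dtype=np.uint8)
        stack = FrameStack(np.stack([frame] * 2), np.arange(2.0))
        out = estimate_raw_bvp(stack, "mean_intensity")
        np.testing.assert_allclose(out.values, [25.0, 25.0])

    def test_unknown_method_rejected(self):
        frame = np.zeros((4, 4), dtype=np.uint8)
        stack = FrameStack(np.stack([frame] * 2), np.arange(2.0))
        with pytest.raises(ConfigurationError):
            estimate_raw_bvp(stack, "green_channel")

    def test_dominant_frequency_matches_planted_pulse(self):
        rr = generate_rr(RRParams(mean_rr=833.0, sdpp_target=0.0,
                                  rmssd_target=0.0, duration=20.0, seed=0))
        stack = render_ppg_frames(rr, seed=1)
        out = estimate_raw_bvp(stack)
        x = out.values - out.values.mean()
        freqs = np.fft.rfftfreq(len(x), d=1 / 30.0)
        peak = freqs[np.abs(np.fft.rfft(x)).argmax()]
        assert peak == pytest.approx(1000.0 / 833.0, rel=0.05)


class TestResampleUniform:
    def test_reproduces_knots_of_uniform_input(self):
        t = np.arange(8) / 4.0
        values = np.array([0.0, 1, 0, -1, 0, 1, 0, -1])
        out = resample_uniform(EntropySignal(values, t), rate=4.0)
        np.testing.assert_allclose(out.values, values, atol=1e-12)

    def test_linear_ramp_exact_on_new_grid(self, rng):
        t = np.sort(rng.uniform(0, 10, 40))
        t[0], t[-1] = 0.0, 10.0
        out = resample_uniform(EntropySignal(3.0 * t + 1.0, t), rate=32.0)
        np.testing.assert_allclose(out.values, 3.0 * out.times + 1.0,
                                   atol=1e-9)

    def test_sinusoid_recovered_from_jittered_sampling(self, rng):
        t = np.cumsum(rng.uniform(0.8, 1.2, 600) / 30.0)
        x = np.sin(2 * np.pi * 1.2 * t)
        out = resample_uniform(EntropySignal(x, t), rate=256.0)
        expected = np.sin(2 * np.pi * 1.2 * out.times)
        assert np.abs(out.values - expected).max() < 1e-2

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            resample_uniform(EntropySignal([1.0, 2, 3], [0.0, 1, 2]), 256.0)


class TestEqualizeAmplitude:
    def test_constant_signal_zeroed(self):
        bvp = BvpSignal(np.full(512, 3.3), rate=256.0)
        out = equalize_amplitude(bvp, 1.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_dc_removed_from_sinusoid(self):
        t = np.arange(0, 10, 1 / 256)
        bvp = BvpSignal(np.sin(2 * np.pi * 1.0 * t) + 5.0, rate=256.0)
        out = equalize_amplitude(bvp, 1.0)  # window = one period
        interior = out.values[256:-256]
        assert abs(interior.mean()) < 1e-3

    def test_matches_brute_force_loop(self, rng):
        x = rng.standard_normal(200)
        bvp = BvpSignal(x, rate=50.0)
        k = 25  # 0.5 s at 50 Hz
        out = equalize_amplitude(bvp, 0.5)
        half_lo, half_hi = (k - 1) // 2, k // 2
        expected = np.array([
            x[i] - x[max(0, i - half_lo):min(len(x), i + half_hi + 1)].mean()
            for i in range(len(x))
        ])
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            equalize_amplitude(BvpSignal(np.ones(100), rate=256.0), 1.0)


class TestDetectPpIntervals:
    def test_sinusoid_intervals_match_period(self, uniform_bvp):
        pp = detect_pp_intervals(uniform_bvp, 0.5)
        assert len(pp) >= 20
        np.testing.assert_allclose(pp.intervals, 1000.0 / 1.2, atol=3.91)

    def test_monotone_ramp_yields_empty_series_with_warning(self):
        bvp = BvpSignal(np.linspace(0, 1, 1024), rate=256.0)
        with pytest.warns(UserWarning):
            pp = detect_pp_intervals(bvp, 0.5)
        assert len(pp) == 0 and pp.warning is not None

    def test_planted_interval_list_recovered(self):
        planted = np.array([820.0, 790.0, 850.0, 810.0])
        beats = np.concatenate(([0.5], 0.5 + np.cumsum(planted) / 1000.0))
        t = np.arange(0, beats[-1] + 0.5, 1 / 256)
        x = np.zeros_like(t)
        for tb in beats:
            x += np.exp(-((t - tb) ** 2) / (2 * 0.05**2))
        pp = detect_pp_intervals(BvpSignal(x, rate=256.0), 0.5)
        np.testing.assert_allclose(pp.intervals, planted, atol=1000 / 256)

    def test_validity_filter_flags_out_of_range(self):
        # peaks 400 ms apart -> all intervals below the 500 ms floor
        t = np.arange(0, 4, 1 / 256)
        x = np.sin(2 * np.pi * 2.5 * t)
        pp = detect_pp_intervals(BvpSignal(x, rate=256.0), 0.3)
        assert len(pp) > 0 and not pp.valid.any()


class TestExtractPpg:
    def test_planted_rr_recovered_end_to_end(self):
        rr = generate_rr(RRParams(850.0, 40.0, 30.0, 20.0, seed=5))
        stack = render_ppg_frames(rr, seed=6)
        _, pp = extract_ppg(stack)
        n = min(len(pp), len(rr))
        assert n >= len(rr) - 1
        err = np.abs(pp.intervals[:n] - rr.intervals[:n])
        assert err.mean() <= 4.0

    def test_constant_stack_warns_and_returns_empty(self):
        frame = np.full((8, 8), 100, dtype=np.uint8)
        stack = FrameStack(np.stack([frame] * 200), np.arange(200) / 30.0)
        with pytest.warns(UserWarning):
            _, pp = extract_ppg(stack)
        assert len(pp) == 0

    def test_pipeline_is_deterministic(self):
        rr = generate_rr(RRParams(seed=3))
        stack = render_ppg_frames(rr, seed=4)
        bvp1, pp1 = extract_ppg(stack)
        bvp2, pp2 = extract_ppg(stack)
        np.testing.assert_array_equal(bvp1.values, bvp2.values)
        np.testing.assert_array_equal(pp1.intervals, pp2.intervals)

    def test_stage_errors_carry_stage_name(self):
        frame = np.zeros((4, 4), dtype=np.uint8)
        stack = FrameStack(np.stack([frame] * 3), np.arange(3.0))
        with pytest.raises(PipelineStageError, match="resample_uniform"):
            extract_ppg(stack, PpgConfig())
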