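import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ortune.imaging_io import AcquisitionProtocol, ROISet
from ortune.synthetic import BleachModel, SimulationConfig, simulate_ratiometric_stack, simulate_trace
from ortune.traces import (
    DeltaTrace,
    FluorescenceTrace,
    blank_subtraction,
    delta_f_over_f0,
    delta_r_over_r,
    log_bleach_correction,
    median_filter_3,
    ratio_timeseries,
    response_amplitude,
    bee_pipeline,
    fly_pipeline,
)


def make_trace(values, protocol):
    return FluorescenceTrace(np.asarray(values, dtype=float), protocol)


class TestDeltaF:
    def test_constant_trace_gives_zeros(self, fly_protocol):
        d = delta_f_over_f0(make_trace(np.full(100, 50.0), fly_protocol))
        np.testing.assert_allclose(d.values, 0.0)
        assert d.baseline_value == 50.0

    def test_ten_percent_step(self, fly_protocol):
        values = np.full(100, 100.0)
        values[16:31] = 110.0
        d = delta_f_over_f0(make_trace(values, fly_protocol))
        np.testing.assert_allclose(d.values[16:31], 0.10)
        np.testing.assert_allclose(d.values[9:14], 0.0)

    def test_nonpositive_baseline_rejected(self, fly_protocol):
        with pytest.raises(ValueError, match="baseline"):
            delta_f_over_f0(make_trace(np.zeros(100), fly_protocol))

    @given(gain=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance(self, gain):
        """dF/F0 is unchanged when the raw trace is scaled by any gain."""
        protocol = AcquisitionProtocol()
        rng = np.random.default_rng(7)
        values = rng.uniform(50, 150, size=100)
        d1 = delta_f_over_f0(make_trace(values, protocol))
        d2 = delta_f_over_f0(make_trace(gain * values, protocol))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_matches_planted_transient_noiseless(self, clean_config):
        trace, truth = simulate_trace(clean_config, 0.07, convention="fly")
        d = delta_f_over_f0(trace)
        kernel = clean_config.transient.kernel(100, 15)
        np.testing.assert_allclose(d.values, truth.amplitude * kernel, atol=1e-12)


class TestBlankSubtraction:
    def test_identical_traces_cancel(self, bleached_config):
        blank, _ = simulate_trace(bleached_config, 0.0, convention="fly")
        d = delta_f_over_f0(blank)
        np.testing.assert_allclose(blank_subtraction(d, d).values, 0.0)

    def test_boxcar_survives_exactly(self, fly_protocol):
        base = np.linspace(0, -0.05, 100)
        boxcar = np.zeros(100)
        boxcar[16:31] = 0.05
        d = DeltaTrace(base + boxcar, 1.0, fly_protocol)
        b = DeltaTrace(base, 1.0, fly_protocol)
        np.testing.assert_allclose(blank_subtraction(d, b).values, boxcar, atol=1e-15)

    def test_length_mismatch_rejected(self, fly_protocol):
        d = DeltaTrace(np.zeros(100), 1.0, fly_protocol)
        b = DeltaTrace(np.zeros(50), 1.0, fly_protocol)
        with pytest.raises(ValueError, match="length"):
            blank_subtraction(d, b)

    def test_bleach_on_recovery_noiseless(self, bleached_config):
        trace, truth = simulate_trace(bleached_config, 0.05, convention="fly")
        blank, _ = simulate_trace(bleached_config, 0.0, convention="fly")
        amp = fly_pipeline(trace, blank)
        # the bleach factor scales the transient slightly between baseline
        # and response windows; recovery is within 2% relative
        assert abs(amp.value - truth.amplitude) / truth.amplitude < 0.02


class TestRatio:
    def test_proportional_channels_give_zero(self, bee_protocol):
        f380 = np.random.default_rng(0).uniform(100, 200, size=100)
        rt = ratio_timeseries(2.0 * f380, f380, bee_protocol)
        np.testing.assert_allclose(rt.r_values, 2.0)
        d = delta_r_over_r(rt)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-14)

    def test_anticorrelated_five_percent(self, bee_protocol):
        f340 = np.full(100, 100.0)
        f380 = np.full(100, 100.0)
        f340[16:19] *= 1.05
        f380[16:19] *= 0.95
        d = delta_r_over_r(ratio_timeseries(f340, f380, bee_protocol))
        np.testing.assert_allclose(d.values[16:19], 1.05 / 0.95 - 1.0)  # ~ +10.5%

    def test_channel_swap_inverts_sign(self, clean_config, bee_protocol):
        rois = ROISet.from_rectangles({"a": (4, 4, 12, 12)})
        s340, s380, rois, truth = simulate_ratiometric_stack(clean_config, rois, {"a": 0.02})
        normal = bee_pipeline(s340, s380, rois, bee_protocol, median_filter=False, bleach="none")
        swapped = bee_pipeline(s380, s340, rois, bee_protocol, median_filter=False, bleach="none")
        assert normal["a"].value > 0 > swapped["a"].value

    def test_nonpositive_f380_masked_with_warning(self, bee_protocol):
        f340 = np.full(100, 100.0)
        f380 = np.full(100, 100.0)
        f380[50] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            rt = ratio_timeseries(f340, f380, bee_protocol)
        assert rt.n_masked == 1 and np.isnan(rt.r_values[50])

    def test_nonpositive_f380_in_baseline_is_error(self, bee_protocol):
        f340 = np.full(100, 100.0)
        f380 = np.full(100, 100.0)
        f380[10] = -1.0
        with pytest.raises(ValueError, match="baseline"):
            ratio_timeseries(f340, f380, bee_protocol)


class TestMedianFilter:
    def test_constant_unchanged(self):
        x = np.full((10, 10, 10), 3.0)
        np.testing.assert_array_equal(median_filter_3(x), x)

    def test_temporal_median_center(self):
        out = median_filter_3(np.array([1.0, 5.0, 1.0]))
        assert out[1] == 1.0

    def test_matches_bruteforce_per_axis_oracle(self, rng):
        def brute(a):
            out = a.copy()
            for ax in (2, 1, 0):  # x, y, t
                padded = np.concatenate(
                    [np.take(out, [0], axis=ax), out, np.take(out, [-1], axis=ax)], axis=ax
                )
                stacked = np.stack(
                    [
                        np.take(padded, range(i, i + out.shape[ax]), axis=ax)
                        for i in range(3)
                    ]
                )
                out = np.median(stacked, axis=0)
            return out

        for _ in range(5):
            a = rng.normal(size=(10, 10, 10))
            np.testing.assert_array_equal(median_filter_3(a), brute(a))

    def test_never_widens_value_range(self, rng):
        a = rng.normal(size=(8, 8, 8))
        out = median_filter_3(a)
        assert out.min() >= a.min() and out.max() <= a.max()

    def test_short_axis_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = median_filter_3(np.ones((2, 5, 5)))
        assert out.shape == (2, 5, 5)


class TestLogBleachCorrection:
    def test_pure_log_decay_removed(self, bee_protocol):
        t = np.arange(100.0)
        d = DeltaTrace(0.03 - 0.012 * np.log(t + 1), 1.0, bee_protocol)
        out = log_bleach_correction(d)
        assert np.sqrt(np.mean(out.values**2)) < 1e-8

    def test_boxcar_inside_exclusion_recovered(self, bee_protocol):
        t = np.arange(100.0)
        boxcar = np.zeros(100)
        boxcar[16:19] = 0.01
        d = DeltaTrace(0.02 - 0.008 * np.log(t + 1) + boxcar, 1.0, bee_protocol)
        out = log_bleach_correction(d)
        amp = out.values[16:19].mean() - out.values[8:11].mean()
        assert abs(amp - 0.01) / 0.01 < 0.02

    def test_flat_input_warns_and_zeroes(self, bee_protocol):
        d = DeltaTrace(np.full(100, 0.5), 1.0, bee_protocol)
        with pytest.warns(UserWarning, match="constant"):
            out = log_bleach_correction(d)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_exponential_variant_removes_exp_decay(self, bee_protocol):
        t = np.arange(100.0)
        d = DeltaTrace(0.05 * np.exp(-t / 40.0) - 0.02, 1.0, bee_protocol)
        out = log_bleach_correction(d, model="exp")
        assert np.sqrt(np.mean(out.values**2)) < 1e-6


class TestResponseAmplitude:
    def test_zero_trace_zero_amplitude(self, bee_protocol):
        d = DeltaTrace(np.zeros(100), 1.0, bee_protocol)
        assert response_amplitude(d, "bee").value == 0.0

    def test_bee_offset_invariance(self, bee_protocol):
        values = np.zeros(100)
        values[16:19] = 1.0
        d = DeltaTrace(values, 1.0, bee_protocol)
        assert response_amplitude(d, "bee").value == pytest.approx(1.0)
        d_off = DeltaTrace(values + 0.37, 1.0, bee_protocol)
        assert response_amplitude(d_off, "bee").value == pytest.approx(1.0)

    def test_unknown_convention_rejected(self, bee_protocol):
        with pytest.raises(ValueError, match="convention"):
            response_amplitude(DeltaTrace(np.zeros(100), 1.0, bee_protocol), "mouse")

    @pytest.mark.parametrize("convention", ["fly", "bee"])
    def test_noiseless_generator_recovery(self, clean_config, convention):
        trace, truth = simulate_trace(clean_config, 0.03, convention=convention)
        amp = response_amplitude(delta_f_over_f0(trace), convention)
        assert amp.value == pytest.approx(truth.amplitude, rel=1e-10)


class TestBeePipelineOnStacks:
    def test_planted_amplitudes_recovered(self, clean_config, bee_protocol):
        rois = ROISet.from_rectangles({"mg2": (5, 5, 16, 16), "bg": (30, 5, 45, 20)})
        s340, s380, rois, truth = simulate_ratiometric_stack(
            clean_config, rois, {"mg2": 0.01, "bg": 0.0}
        )
        amps = bee_pipeline(s340, s380, rois, bee_protocol, bleach="none")
        assert amps["mg2"].value == pytest.approx(0.01, rel=1e-6)
        assert abs(amps["bg"].value) < 1e-9

    def test_only_planted_roi_exceeds_half_percent(self, bleached_config, bee_protocol):
        rois = ROISet.from_rectangles({"a": (5, 5, 16, 16), "b": (30, 5, 45, 20)})
        s340, s380, rois, _ = simulate_ratiometric_stack(bleached_config, rois, {"a": 0.01, "b": 0.0})
        amps = bee_pipeline(s340, s380, rois, bee_protocol)
        assert amps["a"].percent > 0.5 and abs(amps["b"].percent) < 0.5

    def test_overlapping_rois_rejected(self, clean_config):
        rois = ROISet.from_rectangles({"a": (5, 5, 16, 16), "b": (10, 10, 20, 20)})
        with pytest.raises(ValueError, match="overlap"):
            simulate_ratiometric_stack(clean_config, rois, {"a": 0.01})

    def test_traces_match_generator_means(self, clean_config):
        from ortune.imaging_io import extract_roi_traces

        rois = ROISet.from_rectangles({"a": (4, 4, 10, 10)})
        s340, _s380, rois, _ = simulate_ratiometric_stack(clean_config, rois, {"a": 0.02})
        traces = extract_roi_traces(s340, rois)
        mask = rois.mask("a", s340.shape)
        expected = s340.pixels[:, mask].mean(axis=1)
        np.testing.assert_allclose(traces["a"].to_numpy(), expected, atol=1e-9)
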