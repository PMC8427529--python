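import dataclasses

import numpy as np
import pytest

from lamincycle.cp_analysis import (
    CPTrace,
    NoLaserOnEdgeError,
    aggregate_free_fraction,
    analyze_trace,
    cp_model,
    detect_t0,
    fit_cp,
    preprocess,
    read_traces_csv,
    window_to_samples,
    write_traces_csv,
)
from lamincycle.synthetic_data import CP_PRESETS, CPSimConfig, simulate_cp_trace


def model_trace(a, b, c, d, duration=60.0, fs=20.0, baseline_s=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n_pre = int(round(baseline_s * fs))
    t = np.arange(n_pre + int(duration * fs) + 1) / fs
    y = np.full(t.size, 0.03)
    tr = np.arange(t.size - n_pre) / fs
    y[n_pre:] = cp_model(tr, a, b, c, d)
    if noise:
        y = y + rng.normal(0, noise, t.size)
    return CPTrace(time=t, intensity=np.clip(y, 0, None))


class TestDetectT0:
    def test_step_trace_maximal_difference(self):
        trace = CPTrace(np.arange(6.0), np.array([0.0, 0.0, 0.0, 10.0, 9.5, 9.0]))
        assert detect_t0(trace) == 3

    def test_trace_starting_at_peak_warns_and_returns_zero(self):
        trace = CPTrace(np.arange(50.0) / 10, np.exp(-np.arange(50) / 20.0))
        with pytest.warns(UserWarning):
            assert detect_t0(trace) == 0

    def test_injected_t0_recovered_within_one_sample(self):
        cfg = CP_PRESETS["G1"]
        true_t0 = int(round(cfg.pre_t0_baseline_s * cfg.sampling_rate_hz))
        for seed in range(5):
            trace = simulate_cp_trace(cfg, seed)
            assert abs(detect_t0(trace) - true_t0) <= 1

    def test_no_edge_raises(self):
        # slow monotone drift: no single difference carries the jump
        trace = CPTrace(np.arange(100.0), np.linspace(1.0, 2.0, 100))
        with pytest.raises(NoLaserOnEdgeError):
            detect_t0(trace)


class TestPreprocess:
    def test_constant_trace_normalizes_to_one(self):
        trace = CPTrace(np.arange(60.0), np.full(60, 5.0))
        with pytest.warns(UserWarning):
            processed, _ = preprocess(trace)
        np.testing.assert_allclose(processed.intensity, 1.0)

    def test_peak_equals_one_for_any_valid_input(self):
        for seed in range(3):
            trace = simulate_cp_trace(CP_PRESETS["S"], seed)
            processed, _ = preprocess(trace)
            assert processed.intensity.max() == pytest.approx(1.0, abs=1e-12)

    def test_smoothing_leaves_smooth_signal_nearly_unchanged(self):
        trace = model_trace(0.3, 0.4, -0.002, 0.7)
        with pytest.warns(UserWarning):  # monotone decay, no rising edge
            processed, _ = preprocess(trace)
        t = processed.time
        expected = cp_model(t, 0.3, 0.4, -0.002, 0.7)
        np.testing.assert_allclose(
            processed.intensity, expected / expected[0], rtol=1e-4
        )

    def test_window_conversion_rounds_half_up_to_odd(self):
        assert window_to_samples(0.1, 1.0) == 1
        assert window_to_samples(0.1, 0.05) == 3  # 2 samples, forced odd
        assert window_to_samples(0.25, 0.05) == 5


class TestFitCP:
    @pytest.mark.parametrize(
        "a,b,c,d,expected_ff",
        [
            (0.25, 0.5, -0.002, 0.75, 0.75),
            (0.0, 1.0, -0.003, 1.0, 1.0),  # pure linear decay: all free
            (1.0, 0.5, 0.0, 0.0, 0.0),  # pure exponential: all bound
        ],
    )
    def test_noiseless_parameter_recovery(self, a, b, c, d, expected_ff):
        trace = model_trace(a, b, c, d, baseline_s=1.0)
        result = analyze_trace(trace)
        assert result.converged
        assert result.free_fraction == pytest.approx(expected_ff, abs=1e-3)
        assert result.rss < 1e-6

    def test_free_fraction_always_in_unit_interval(self):
        for seed in range(10):
            trace = simulate_cp_trace(CP_PRESETS["S"], seed)
            result = analyze_trace(trace)
            if result.converged:
                assert 0.0 <= result.free_fraction <= 1.0

    def test_amplitudes_sum_near_one_after_normalization(self):
        for seed in range(5):
            result = analyze_trace(simulate_cp_trace(CP_PRESETS["G1"], seed))
            assert result.a + result.d == pytest.approx(1.0, abs=0.05)

    def test_slow_bleach_rate_flagged_ill_conditioned(self):
        trace = model_trace(0.3, 0.005, -0.001, 0.7, baseline_s=1.0)
        result = analyze_trace(trace)
        assert result.ill_conditioned

    def test_increasing_bound_fraction_decreases_estimate_monotonically(self):
        """Rank test over 5 bound-fraction levels."""
        means = []
        for f in (0.9, 0.8, 0.7, 0.6, 0.5):
            cfg = dataclasses.replace(CP_PRESETS["G1"], true_free_fraction=f)
            ests = [analyze_trace(simulate_cp_trace(cfg, s)).free_fraction for s in range(8)]
            means.append(float(np.mean(ests)))
        assert np.all(np.diff(means) < 0)  # strictly decreasing


class TestAggregate:
    def _result(self, ff):
        from lamincycle.cp_analysis import CPFitResult

        return CPFitResult("c", "G1", 1 - ff, 0.3, -0.002, ff, ff, 0, 0.0, True)

    def test_mean_and_sample_std_in_percent(self):
        s = aggregate_free_fraction([self._result(0.8), self._result(0.9)])
        assert s.mean_percent == pytest.approx(85.0)
        assert s.std_percent == pytest.approx(100 * np.std([0.8, 0.9], ddof=1))

    def test_single_converged_fit_rejected(self):
        with pytest.raises(ValueError):
            aggregate_free_fraction([self._result(0.8)])

    def test_mean_curve_band_from_traces(self):
        traces = [preprocess(simulate_cp_trace(CP_PRESETS["G1"], s))[0] for s in range(3)]
        results = [fit_cp(tr) for tr in traces]
        s = aggregate_free_fraction(results, traces=traces)
        assert s.curve_mean is not None
        assert s.curve_mean.shape == s.curve_std.shape == s.curve_time.shape
        assert s.curve_mean[0] == pytest.approx(1.0, abs=0.05)


class TestTraceValidation:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            CPTrace(np.array([0.0, 1.0, 0.5]), np.ones(3))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            CPTrace(np.arange(3.0), np.array([1.0, -0.1, 0.5]))

    def test_acquisition_check_flags_short_traces(self):
        trace = CPTrace(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            trace.validate_acquisition()
        simulate_cp_trace(CP_PRESETS["G1"], 0).validate_acquisition()


def test_traces_csv_roundtrip(tmp_path):
    traces = [simulate_cp_trace(CP_PRESETS["G1"], s, cell_id=f"c{s}", label="G1") for s in range(3)]
    path = tmp_path / "traces.csv"
    write_traces_csv(traces, path)
    back = read_traces_csv(path)
    assert [t.cell_id for t in back] == ["c0", "c1", "c2"]
    np.testing.assert_allclose(back[0].intensity, traces[0].intensity)
    assert back[0].label == "G1"
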