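"""dF/F, event detection, T* estimation, binned fractions, comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormtherm import calcium_quant as cq
from wormtherm import synthetic_worlds as sw
from wormtherm.stimulus import TemperatureRamp


def make_trace(fluor, frame_rate=2.0, temperature=None, neuron_id="n"):
    fluor = np.asarray(fluor, dtype=float)
    times = np.arange(len(fluor)) / frame_rate
    return cq.CalciumTrace(neuron_id, times, fluor, temperature=temperature,
                           frame_rate=frame_rate)


def make_dff(values, frame_rate=2.0, temperature=None):
    values = np.asarray(values, dtype=float)
    return cq.DffTrace(np.arange(len(values)) / frame_rate, values, 100.0,
                       frame_rate=frame_rate, temperature=temperature)


class TestDff:
    def test_constant_trace_zero(self):
        d = cq.dff(make_trace([100.0] * 50))
        assert np.allclose(d.dff, 0.0)
        assert d.baseline_value == pytest.approx(100.0)

    def test_step_gives_25_percent(self):
        d = cq.dff(make_trace([100.0] * 10 + [125.0] * 20))
        assert np.allclose(d.dff[:10], 0.0, atol=1e-9)
        assert np.allclose(d.dff[10:], 25.0, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            # length 10 == baseline window, must strictly exceed it
            cq.dff(make_trace([100.0] * 10))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="background"):
            cq.dff(make_trace([-1.0] * 10 + [5.0] * 10))

    def test_offset_invariance_post_dff(self):
        # events detected on dF/F are invariant to rescaling raw fluorescence
        base = np.array([100.0] * 10 + [130.0] * 20 + [100.0] * 20)
        e1 = cq.detect_events(cq.dff(make_trace(base)))
        e2 = cq.detect_events(cq.dff(make_trace(base * 3.7)))
        assert [(e.onset_time, e.offset_time) for e in e1] == [
            (e.onset_time, e.offset_time) for e in e2
        ]


class TestDetrend:
    def test_linear_drift_removed(self):
        t = np.arange(480) / 2.0
        temp = 16.0 + 0.05 * t
        d = make_dff(5.0 + 0.1 * t, temperature=temp)
        out = cq.detrend_peri_tc(d, (18.0, 22.0))
        assert np.max(np.abs(out.dff)) < 1e-6
        assert abs(out.dff.mean()) < 1e-9

    def test_window_times_on_standard_ramp(self):
        # [18, 22] degC on a 16 degC + 0.05 degC/s ramp -> t in [40, 120] s
        t = np.arange(480) / 2.0
        d = make_dff(np.zeros(480), temperature=16.0 + 0.05 * t)
        out = cq.detrend_peri_tc(d, (18.0, 22.0))
        assert out.times[0] == pytest.approx(40.0)
        assert out.times[-1] == pytest.approx(120.0)

    def test_pulse_survives_detrending(self):
        t = np.arange(480) / 2.0
        temp = 16.0 + 0.05 * t
        y = 0.1 * t  # drift
        y[150:170] += 30.0  # 30% square pulse inside the window
        out = cq.detrend_peri_tc(make_dff(y, temperature=temp), (18.0, 22.0))
        assert len(cq.detect_events(out)) == 1

    def test_requires_temperature_channel(self):
        with pytest.raises(ValueError, match="temperature"):
            cq.detrend_peri_tc(make_dff(np.zeros(100)), (18.0, 22.0))

    def test_window_outside_range_rejected(self):
        t = np.arange(100) / 2.0
        d = make_dff(np.zeros(100), temperature=16.0 + 0.05 * t)
        with pytest.raises(ValueError, match="outside recorded"):
            cq.detrend_peri_tc(d, (25.0, 26.0))


class TestDetectEvents:
    def test_subthreshold_empty(self):
        assert cq.detect_events(make_dff([5.0] * 100)) == []

    def test_single_pulse_duration(self):
        # 30 s pulse at 20% sampled at 2 Hz
        vals = [0.0] * 20 + [20.0] * 60 + [0.0] * 20
        events = cq.detect_events(make_dff(vals))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(30.0, abs=0.5)
        assert events[0].peak_dff == pytest.approx(20.0)

    def test_merge_rule(self):
        # two 10 s pulses separated by one subthreshold frame merge to ~20.5 s
        vals = [0.0] * 10 + [20.0] * 20 + [0.0] + [20.0] * 20 + [0.0] * 10
        events = cq.detect_events(make_dff(vals), merge_gap=1)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(20.5, abs=1e-9)

    def test_no_merge_when_gap_zero(self):
        vals = [0.0] * 10 + [20.0] * 20 + [0.0] + [20.0] * 20 + [0.0] * 10
        events = cq.detect_events(make_dff(vals), merge_gap=0)
        assert len(events) == 2

    def test_min_duration_discards_blips(self):
        vals = [0.0] * 10 + [20.0] + [0.0] * 10
        assert cq.detect_events(make_dff(vals), min_duration=2, merge_gap=0) == []

    def test_strict_threshold(self):
        # dF/F exactly at threshold is not a response (> is strict)
        assert cq.detect_events(make_dff([10.0] * 50), threshold=10.0) == []

    def test_onset_temperature_attached(self):
        t = np.arange(100) / 2.0
        temp = 16.0 + 0.05 * t
        vals = np.zeros(100)
        vals[40:60] = 25.0
        events = cq.detect_events(make_dff(vals, temperature=temp))
        assert events[0].onset_temperature == pytest.approx(temp[40])

    @given(st.floats(5.0, 40.0), st.floats(5.0, 40.0))
    @settings(deadline=None, max_examples=30)
    def test_raising_threshold_never_increases_total(self, th1, th2):
        rng = np.random.default_rng(0)
        vals = 30.0 * np.abs(np.sin(np.arange(200) / 10.0)) + rng.normal(0, 2, 200)
        lo, hi = sorted((th1, th2))
        total = lambda th: sum(
            e.duration for e in cq.detect_events(make_dff(vals), threshold=th)
        )
        assert total(hi) <= total(lo) + 1e-9

    def test_total_duration_sums_exactly(self):
        vals = np.zeros(300)
        vals[20:50] = 15.0
        vals[100:130] = 25.0
        vals[200:280] = 12.0
        events = cq.detect_events(make_dff(vals))
        s = cq.summarize_neuron("n", events)
        assert s.total_response_duration == sum(e.duration for e in events)
        assert s.mean_event_duration == pytest.approx(
            s.total_response_duration / s.n_events
        )


class TestTStar:
    def test_linear_map(self):
        ramp = TemperatureRamp(16.0, 0.05, duration=240.0)
        ev = cq.ResponseEvent(120.0, 130.0, peak_dff=50.0)
        assert cq.t_star([ev], ramp) == pytest.approx(22.0)

    def test_onset_at_zero_gives_start_temp(self):
        ramp = TemperatureRamp(16.0, 0.05, duration=240.0)
        ev = cq.ResponseEvent(0.0, 10.0, peak_dff=50.0)
        assert cq.t_star([ev], ramp) == pytest.approx(16.0)

    def test_no_events_sentinel(self):
        ramp = TemperatureRamp(16.0, 0.05, duration=240.0)
        assert cq.t_star([], ramp) is None

    def test_constant_stimulus_rejected(self):
        ramp = TemperatureRamp(20.0, 0.0, duration=240.0)
        with pytest.raises(ValueError):
            cq.t_star([cq.ResponseEvent(0.0, 1.0, peak_dff=20.0)], ramp)

    def test_round_trip_against_generator(self):
        # programmed onset 22.8 degC recovered within one frame of ramp
        ramp = TemperatureRamp(16.0, 0.05, duration=240.0)
        p = sw.CalciumSimParams(
            deterministic_onset_temp=22.8, noise_sd=0.0, event_amplitude=1.5
        )
        trace, _ = sw.simulate_calcium(p, ramp)
        star = cq.t_star(cq.detect_events(cq.dff(trace)), ramp)
        assert star == pytest.approx(22.8, abs=0.05)


class TestBinResponseFraction:
    def test_no_responses_all_zero(self):
        traces = [(make_dff(np.zeros(480)), []) for _ in range(5)]
        df = cq.bin_response_fraction(traces)
        assert (df["fraction_responding"] == 0.0).all()

    def test_four_minute_trace_sixteen_bins(self):
        traces = [(make_dff(np.zeros(480)), [])]
        assert len(cq.bin_response_fraction(traces, bin_width=15.0)) == 16

    def test_shared_event_fills_bin(self):
        ev = cq.ResponseEvent(30.0, 40.0, peak_dff=20.0)
        traces = [(make_dff(np.zeros(480)), [ev]) for _ in range(10)]
        df = cq.bin_response_fraction(traces)
        row = df[df["bin_start_s"] == 30.0]
        assert row["fraction_responding"].item() == pytest.approx(1.0)
        assert df[df["bin_start_s"] == 60.0]["fraction_responding"].item() == 0.0

    def test_inconsistent_lengths_rejected(self):
        traces = [(make_dff(np.zeros(480)), []), (make_dff(np.zeros(100)), [])]
        with pytest.raises(ValueError, match="time base"):
            cq.bin_response_fraction(traces)


def _brute_force_mwu_p(a, b):
    """Exact two-sided MWU p by enumerating all rank assignments."""
    pooled = np.asarray(a + b, dtype=float)
    n1 = len(a)

    def u_of(idx):
        sa = pooled[list(idx)]
        sb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in sa for y in sb)

    u_obs = u_of(range(n1))
    n = len(pooled)
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    mean_u = len(a) * len(b) / 2
    return float(
        np.mean([abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us])
    )


class TestCompareDistributions:
    def test_identical_samples_ks_zero(self):
        r = cq.compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "ks")
        assert r.statistic == pytest.approx(0.0)

    def test_mwu_complete_separation_exact_p(self):
        r = cq.compare_distributions([1, 2, 3], [10, 20, 30], "mwu")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.p_value == pytest.approx(_brute_force_mwu_p([1, 2, 3], [10, 20, 30]))

    def test_ecdf_curves_emitted(self):
        r = cq.compare_distributions([3.0, 1.0, 2.0], [5.0], "ks")
        xs, fs = r.ecdf_a
        assert list(xs) == [1.0, 2.0, 3.0]
        assert fs[-1] == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cq.compare_distributions([], [1.0], "ks")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            cq.compare_distributions([1.0], [2.0], "median")

    @pytest.mark.parametrize("test", ["ks", "mwu"])
    def test_type_one_error_calibrated(self, test, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            if cq.compare_distributions(a, b, test).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09
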