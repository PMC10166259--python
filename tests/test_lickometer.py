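"""Detection pipeline: filtering oracles, peak rules, matching, metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freilick.errors import ParameterError
from freilick.events import LickEventSeries
from freilick.lickometer import (
    MatchResult,
    OfflineParams,
    OnlineParams,
    confusion_metrics,
    detect_licks_offline,
    emulate_online_comparator,
    interlick_intervals,
    match_licks,
    preprocess,
    threshold_sweep,
)
from freilick.synthetic import NoiseSpec, gen_sg_trace, raised_cosine
from freilick.trace import SGTrace


def bump_trace(centers, amps, fs=10_000.0, width=0.12, duration=None, baseline=0.0):
    if duration is None:
        duration = max(centers) + 1.0
    t = np.arange(int(duration * fs)) / fs
    x = np.full(t.size, baseline)
    for c, a in zip(centers, amps):
        x += a * raised_cosine(t, c, width)
    return SGTrace(samples=x, fs_hz=fs)


class TestPreprocess:
    def test_constant_trace_stays_constant(self):
        tr = SGTrace(samples=np.full(30_000, 0.25), fs_hz=30_000)
        out = preprocess(tr)
        assert out.fs_hz == 1000
        np.testing.assert_allclose(out.samples, 0.25, atol=1e-6)

    def test_passband_sine_amplitude_preserved(self):
        # 10 Hz is far inside the 64 Hz passband: amplitude within 1%
        t = np.arange(0, 4, 1 / 30_000)
        tr = SGTrace(samples=np.sin(2 * np.pi * 10 * t), fs_hz=30_000)
        out = preprocess(tr)
        mid = out.samples[500:-500]  # ignore filter edges
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_sine_attenuated(self):
        # 500 Hz is deep in the stopband (>= 40 dB attenuation)
        t = np.arange(0, 4, 1 / 30_000)
        tr = SGTrace(samples=np.sin(2 * np.pi * 500 * t), fs_hz=30_000)
        out = preprocess(tr)
        assert np.abs(out.samples[500:-500]).max() < 0.01

    def test_zero_phase_peak_unbiased(self):
        tr = bump_trace([1.0], [0.3], fs=30_000)
        out = preprocess(tr)
        t_peak = np.argmax(out.samples) / out.fs_hz
        assert abs(t_peak - 1.0) <= 0.002

    def test_low_rate_rejected(self):
        with pytest.raises(ParameterError):
            preprocess(SGTrace(samples=np.zeros(100), fs_hz=500))


class TestOfflineDetection:
    def test_zero_trace_empty(self):
        tr = SGTrace(samples=np.zeros(20_000), fs_hz=10_000)
        assert len(detect_licks_offline(tr)) == 0

    def test_separated_bumps_all_found_at_centers(self):
        centers = 0.5 + 0.150 * np.arange(5)
        tr = bump_trace(centers, [0.1] * 5)
        det = detect_licks_offline(tr)
        assert len(det) == 5
        assert np.all(np.abs(det.times_s - centers) <= 0.005)

    def test_min_distance_rule_keeps_taller_of_close_pair(self):
        # two narrow, resolvable bumps 50 ms apart violate the 60 ms rule:
        # only the taller one survives (width floor relaxed so both peaks
        # exist before the distance rule is applied)
        tr = bump_trace([1.0, 1.05], [0.08, 0.12], width=0.05)
        params = OfflineParams(min_width_s=0.010)
        det = detect_licks_offline(tr, params)
        assert len(det) == 1
        assert abs(det.times_s[0] - 1.05) <= 0.01  # the taller bump

    def test_output_respects_distance_prominence_width(self, validation_scene):
        licks, trace = validation_scene
        params = OfflineParams()
        det = detect_licks_offline(trace, params)
        assert len(det) > 0
        assert np.all(np.diff(det.times_s) >= params.min_distance_s)

    def test_sub_prominence_bumps_ignored(self):
        tr = bump_trace([1.0, 2.0], [0.010, 0.10])
        det = detect_licks_offline(tr)
        assert len(det) == 1


class TestOnlineComparator:
    def test_subthreshold_trace_empty(self):
        tr = SGTrace(samples=np.full(30_000, 0.01), fs_hz=10_000)
        assert len(emulate_online_comparator(tr)) == 0

    def test_rectangular_pulse_single_onset_at_first_crossing(self):
        fs = 10_000
        x = np.zeros(3 * fs)
        x[fs:fs + 500] = 0.15  # 50 ms pulse, 150 mV above flat zero baseline
        tr = SGTrace(samples=x, fs_hz=fs)
        det = emulate_online_comparator(tr)
        assert len(det) == 1
        assert math.isclose(det.times_s[0], 1.0, abs_tol=1e-6)

    def test_default_threshold_is_100mv(self):
        assert OnlineParams().threshold_above_baseline_V == pytest.approx(0.100)

    def test_hysteresis_blocks_refiring_without_rearm(self):
        fs = 10_000
        t = np.arange(4 * fs) / fs
        # oscillates between 0.08 and 0.12 around the 0.10 threshold:
        # only the first crossing fires because it never falls below 0.05
        x = 0.10 + 0.02 * np.sin(2 * np.pi * 5 * t)
        x[: 2 * fs] = 0.0  # quiet lead-in covering the baseline window
        tr = SGTrace(samples=x, fs_hz=fs)
        det = emulate_online_comparator(tr)
        assert len(det) == 1


def brute_force_best_match(det, tru, tol):
    """Independent oracle: exhaustive max-cardinality one-to-one matching."""
    best = {"tp": 0}

    def rec(i, used, tp):
        if tp + (len(det) - i) <= best["tp"]:
            return
        if i == len(det):
            best["tp"] = max(best["tp"], tp)
            return
        for j in range(len(tru)):
            if j not in used and abs(det[i] - tru[j]) < tol:
                rec(i + 1, used | {j}, tp + 1)
        rec(i + 1, used, tp)

    rec(0, frozenset(), 0)
    return best["tp"]


class TestMatching:
    def test_identical_series_all_tp(self):
        t = np.arange(7) * 0.2
        m = match_licks(t, t)
        assert (m.tp, m.fp, m.fn) == (7, 0, 0)

    def test_shift_beyond_tolerance_matches_nothing(self):
        tru = np.arange(5) * 0.2
        det = tru + 0.080  # 80 ms > 60 ms tolerance
        m = match_licks(det, tru)
        assert (m.tp, m.fp, m.fn) == (0, 5, 5)

    def test_nearest_truth_is_paired(self):
        m = match_licks([0.100], [0.130, 0.145])
        assert (m.tp, m.fn, m.fp) == (1, 1, 0)
        assert m.pairs == [(0.100, 0.130)]

    def test_counts_satisfy_invariants(self, rng):
        det = np.sort(rng.uniform(0, 5, 20))
        tru = np.sort(rng.uniform(0, 5, 25))
        m = match_licks(det, tru)
        assert m.tp == len(m.pairs)
        assert m.tp + m.fn == 25
        assert m.tp + m.fp == 20

    def test_greedy_counterexample_handled_optimally(self):
        # closest-first greedy would pair (0.5, 0.4) and strand both others
        m = match_licks([0.0, 0.5], [0.4, 1.4], tolerance_s=1.0)
        assert m.tp == 2

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_d = data.draw(st.integers(0, 8))
        n_t = data.draw(st.integers(0, 8))
        det = sorted(data.draw(st.lists(
            st.floats(0, 2, allow_nan=False), min_size=n_d, max_size=n_d)))
        tru = sorted(data.draw(st.lists(
            st.floats(0, 2, allow_nan=False), min_size=n_t, max_size=n_t)))
        m = match_licks(np.array(det), np.array(tru), tolerance_s=0.3)
        assert m.tp == brute_force_best_match(det, tru, 0.3)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            match_licks([0.0], [0.0], tolerance_s=-1.0)


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,fn,sens,ppv", [
        (3, 0, 1, 0.75, 1.0),
        (3, 1, 0, 1.0, 0.75),
        (0, 5, 5, 0.0, 0.0),
    ])
    def test_formulas(self, tp, fp, fn, sens, ppv):
        m = MatchResult(tp=tp, fp=fp, fn=fn, pairs=[], tolerance_s=0.06)
        out = confusion_metrics(m)
        assert out["sensitivity"] == pytest.approx(sens)
        assert out["ppv"] == pytest.approx(ppv)

    def test_undefined_ratios_are_nan_not_zero(self):
        m = MatchResult(tp=0, fp=0, fn=0, pairs=[], tolerance_s=0.06)
        out = confusion_metrics(m)
        assert math.isnan(out["sensitivity"]) and math.isnan(out["ppv"])


class TestThresholdSweep:
    def test_single_threshold_equals_direct_run(self, validation_scene):
        licks, trace = validation_scene
        table = threshold_sweep(trace, licks, [0.1])
        det = emulate_online_comparator(trace, OnlineParams())
        m = match_licks(det, licks)
        assert table.loc[0, "tp"] == m.tp
        assert table.loc[0, "fp"] == m.fp

    def test_graded_peaks_cross_successive_thresholds(self):
        # peaks 30/50/120 mV over baseline; thresholds 100/40/20 mV
        tr = bump_trace([3.0, 4.0, 5.0], [0.03, 0.05, 0.12], duration=6.0)
        truth = LickEventSeries(times_s=[3.0, 4.0, 5.0])
        table = threshold_sweep(tr, truth, [0.10, 0.04, 0.02])
        assert table["n_detected"].tolist() == [1, 2, 3]

    def test_sensitivity_nonincreasing_in_threshold(self, validation_scene):
        licks, trace = validation_scene
        table = threshold_sweep(trace, licks, np.arange(0.02, 0.15, 0.02))
        sens = table["sensitivity"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)

    def test_fp_nonincreasing_fn_nondecreasing_in_threshold(self, validation_scene):
        licks, trace = validation_scene
        table = threshold_sweep(trace, licks, np.arange(0.02, 0.15, 0.02))
        assert np.all(np.diff(table["fp"].to_numpy()) <= 0)
        assert np.all(np.diff(table["fn"].to_numpy()) >= 0)

    def test_empty_threshold_list_gives_empty_table(self, validation_scene):
        licks, trace = validation_scene
        assert len(threshold_sweep(trace, licks, [])) == 0


class TestInterlickIntervals:
    def test_successive_differences(self):
        iv, _ = interlick_intervals(LickEventSeries(times_s=[0.0, 0.1, 0.2]))
        np.testing.assert_allclose(iv, [0.1, 0.1])

    def test_fewer_than_two_events_empty(self):
        iv, summary = interlick_intervals(LickEventSeries(times_s=[1.0]))
        assert iv.size == 0 and summary["n"] == 0

    def test_offline_series_respects_distance_floor(self, validation_scene):
        licks, trace = validation_scene
        det = detect_licks_offline(trace)
        iv, _ = interlick_intervals(det)
        assert np.all(iv >= 0.060)

    def test_ten_hz_train_mode_near_100ms(self):
        from freilick.synthetic import LickTrainSpec, gen_lick_train
        licks = gen_lick_train(LickTrainSpec(rate_hz=10.0, duration_s=300.0, seed=2))
        _, summary = interlick_intervals(licks, bins=50, range_s=(0.0, 0.5))
        assert abs(summary["mode_s"] - 0.1) < 0.03
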