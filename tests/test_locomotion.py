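"""Locomotion segmentation, movement events and event-locked statistics."""

import numpy as np
import pytest

import photoline as pl
from photoline.locomotion import (InsufficientDataError, compute_acceleration,
                                  detect_accel_events, detect_onsets_offsets,
                                  quintile_analysis, quintile_split,
                                  segment_locomotion, triggered_average,
                                  velocity_tuning, xcorr_traces)

from conftest import kernel_trace


def plateau_velocity(n=6000, start=2000, stop=3000, level=0.3, ramp=20):
    v = np.zeros(n)
    v[start:stop] = level
    v[start - ramp:start] = np.linspace(0, level, ramp)
    v[stop:stop + ramp] = np.linspace(level, 0, ramp)
    return v


class TestAcceleration:
    def test_constant_velocity_zero_acceleration(self):
        a = compute_acceleration(np.full(1000, 0.4))
        np.testing.assert_allclose(a, 0.0, atol=1e-12)

    def test_linear_ramp_interior_slope(self):
        v = np.linspace(0.0, 5.0, 1001)  # slope 0.5 m/s per s at 100 Hz
        a = compute_acceleration(v)
        np.testing.assert_allclose(a[10:-10], 0.5, rtol=1e-9)

    def test_step_integral_equals_step_height(self):
        v = np.zeros(2000)
        v[1000:] = 0.37
        a = compute_acceleration(v)
        # telescoping sum: integral of a equals the smoothed-velocity change
        assert np.sum(a[:-1]) / 100.0 == pytest.approx(0.37, abs=1e-6)


class TestSegmentation:
    def test_zero_velocity_empty_and_fails_total(self):
        mask = segment_locomotion(np.zeros(20000), None)
        assert not mask.locomotion_mask.any()
        assert mask.bout_intervals == []
        assert not mask.pass_total

    def test_plateau_is_one_bout_of_expected_length(self):
        v = plateau_velocity(level=0.3)
        mask = segment_locomotion(v, None)
        assert len(mask.bout_intervals) == 1
        t0, t1 = mask.bout_intervals[0]
        assert (t1 - t0) == pytest.approx(10.0, abs=0.5)

    def test_slow_plateau_rejected_by_mean_velocity(self):
        v = plateau_velocity(level=0.1)
        mask = segment_locomotion(v, None)
        assert mask.bout_intervals == []

    def test_short_rest_merged_into_movement(self):
        v = plateau_velocity(level=0.4)
        v[2500:2530] = 0.0  # 0.3-s rest inside the bout
        mask = segment_locomotion(v, None)
        assert len(mask.bout_intervals) == 1

    def test_post_stimulus_window_removed_from_mask(self):
        v = plateau_velocity(level=0.4)
        mask = segment_locomotion(v, stimulus_times=[22.0])
        # bins in [22, 27] s are masked out even though the mouse runs
        assert not mask.locomotion_mask[2250:2700].any()
        assert mask.locomotion_mask[2100]

    def test_isolated_single_bin_movement_dropped(self):
        v = np.zeros(20000)
        v[5000] = 0.5
        mask = segment_locomotion(v, None)
        assert not mask.locomotion_mask.any()


class TestXCorr:
    def test_autocorrelation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=5000)
        xc = xcorr_traces(x, x)
        assert xc.values[np.argmin(np.abs(xc.lags))] == pytest.approx(1.0)

    def test_delayed_copy_peaks_at_delay(self, rng):
        x = rng.normal(size=20000)
        y = np.roll(x, 20)  # y follows x by 0.2 s
        xc = xcorr_traces(x, y)
        assert xc.lags[np.argmax(xc.values)] == pytest.approx(0.2)
        assert xc.peak > 0.95

    def test_independent_traces_bounded(self):
        rng = np.random.default_rng(123)
        n = 100_000
        xc = xcorr_traces(rng.normal(size=n), rng.normal(size=n))
        assert xc.abs_peak < 4.0 / np.sqrt(n)

    def test_symmetry_under_argument_swap(self, rng):
        x = rng.normal(size=3000)
        y = rng.normal(size=3000) + 0.3 * x
        mask = rng.random(3000) > 0.2
        ab = xcorr_traces(x, y, mask)
        ba = xcorr_traces(y, x, mask)
        np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-10)

    def test_too_few_pairs_raises(self, rng):
        x = rng.normal(size=300)
        mask = np.zeros(300, dtype=bool)
        mask[:120] = True
        with pytest.raises(InsufficientDataError):
            xcorr_traces(x, x, mask)

    def test_values_within_unit_interval(self, rng):
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        mask = rng.random(4000) > 0.4
        xc = xcorr_traces(x, y, mask)
        assert np.all(np.abs(xc.values) <= 1.0 + 1e-12)


def half_sine_accel(n=4000, center=2000, peak=3.0, width_s=0.2):
    a = np.zeros(n)
    w = int(width_s * 100)
    t = np.arange(w)
    a[center - w // 2: center - w // 2 + w] = peak * np.sin(np.pi * t / (w - 1))
    return a


class TestAccelEvents:
    def test_zero_acceleration_no_events(self):
        acc, dec = detect_accel_events(np.zeros(3000))
        assert len(acc) == 0 and len(dec) == 0

    def test_isolated_half_sine_is_one_acceleration(self):
        a = half_sine_accel()
        acc, dec = detect_accel_events(a)
        assert len(acc) == 1 and len(dec) == 0
        # the discrete half-sine grid peaks slightly below the nominal 3.0
        assert acc.peak_values[0] == pytest.approx(3.0, rel=0.02)

    def test_two_close_peaks_both_rejected_by_isolation(self):
        a = half_sine_accel(center=2000, width_s=0.1)
        a += half_sine_accel(center=2020, width_s=0.1)  # peaks 0.2 s apart
        acc, dec = detect_accel_events(a)
        assert len(acc) == 0

    def test_subthreshold_peak_ignored(self):
        a = half_sine_accel(peak=1.5)
        acc, dec = detect_accel_events(a)
        assert len(acc) == 0

    def test_short_event_ignored(self):
        a = half_sine_accel(peak=3.0, width_s=0.03)
        acc, _ = detect_accel_events(a)
        assert len(acc) == 0

    def test_events_respect_mask(self):
        a = half_sine_accel()
        mask = np.ones(a.size, dtype=bool)
        mask[1990:2010] = False
        acc, _ = detect_accel_events(a, mask)
        assert len(acc) == 0


class TestOnsetsOffsets:
    def test_clean_onset_accepted(self):
        # sigmoidal start reaching 0.5 m/s within ~0.4 s, then long plateau
        n = 8000
        v = np.zeros(n)
        t0 = 2000
        rise = 1.0 / (1.0 + np.exp(-np.arange(-20, 20) / 6.0))
        v[t0:t0 + 40] = 0.5 * rise
        v[t0 + 40:t0 + 3000] = 0.5
        v[t0 + 3000:t0 + 3040] = 0.5 * rise[::-1]
        a = compute_acceleration(v)
        bouts = segment_locomotion(v, None)
        onsets, offsets = detect_onsets_offsets(v, a, bouts)
        assert len(onsets) == 1
        assert len(offsets) == 1

    def test_slow_start_rejected(self):
        n = 8000
        v = np.zeros(n)
        t0 = 2000
        v[t0:t0 + 150] = np.linspace(0, 0.45, 150)  # reaches 0.4 at ~1.3 s
        v[t0 + 150:t0 + 3000] = 0.45
        a = compute_acceleration(v)
        bouts = segment_locomotion(v, None)
        onsets, _ = detect_onsets_offsets(v, a, bouts)
        assert len(onsets) == 0

    def test_continuous_running_no_transitions(self):
        v = np.full(8000, 0.5)
        a = compute_acceleration(v)
        bouts = segment_locomotion(v, None)
        onsets, offsets = detect_onsets_offsets(v, a, bouts)
        assert len(onsets) == 0 and len(offsets) == 0


class TestTriggeredAverage:
    def test_constant_trace_mean_is_constant(self):
        ta = triggered_average(np.full(5000, 3.25), [10.0, 20.0, 30.0])
        np.testing.assert_allclose(ta.mean_trace, 3.25)
        assert ta.n_events == 3

    def test_mean_equals_explicit_column_mean(self, rng):
        trace = rng.normal(size=5000)
        events = [5.0, 12.0, 33.0, 41.5]
        ta = triggered_average(trace, events)
        assert ta.per_event_matrix.shape == (4, 201)
        np.testing.assert_allclose(ta.mean_trace,
                                   ta.per_event_matrix.mean(axis=0))

    def test_kernel_recovered_within_noise(self, rng):
        n = 60000
        events = np.arange(30) * 19.0 + 5.0
        trace = kernel_trace(n, (events * 100).astype(int), np.full(30, 10.0))
        trace = trace + rng.normal(0, 1.0, n)
        ta = triggered_average(trace, events)
        truth = kernel_trace(201, [100], [10.0])
        # bound the maximum of 201 per-lag deviations, each ~N(0, SE)
        se = 1.0 / np.sqrt(30)
        assert np.all(np.abs(ta.mean_trace - truth) < 4 * se)

    def test_events_without_full_window_dropped(self):
        ta = triggered_average(np.ones(500), [0.5, 2.5, 4.8])
        assert ta.n_events == 1
        with pytest.raises(InsufficientDataError):
            triggered_average(np.ones(500), [0.1])

    def test_masked_bins_propagate_as_missing(self):
        trace = np.ones(1000)
        mask = np.ones(1000, dtype=bool)
        mask[450:460] = False
        ta = triggered_average(trace, [4.5], mask=mask)
        assert np.isnan(ta.per_event_matrix[0, 100:110]).all()


class TestQuintiles:
    def test_split_counting_rule(self):
        vals = np.arange(23.0)
        groups = quintile_split(vals, np.arange(23.0))
        assert [len(g) for g in groups] == [5, 5, 5, 4, 4]

    def test_ties_broken_by_event_time(self):
        vals = np.zeros(10)
        times = np.arange(10.0)[::-1]
        groups = quintile_split(vals, times)
        # earliest events land in the lowest group
        assert sorted(times[groups[0]]) == [0.0, 1.0]

    def test_identical_events_equal_amplitudes(self):
        n = 40000
        events = pl.EventSet(kind="deceleration",
                             times=np.arange(10) * 35.0 + 10.0,
                             peak_values=np.full(10, -3.0),
                             peak_times=np.arange(10) * 35.0 + 10.1)
        trace = kernel_trace(n, ((events.times + 0.3) * 100).astype(int),
                             np.full(10, 20.0))
        q = quintile_analysis(events, trace)
        assert np.allclose(q.amplitudes, q.amplitudes[0], rtol=1e-6)
        assert q.ratio == pytest.approx(1.0, abs=1e-6)

    def test_amplitude_increases_with_programmed_gain(self):
        n = 60000
        times = np.arange(25) * 22.0 + 10.0
        peaks = -(2.0 + np.linspace(0, 2.5, 25))
        events = pl.EventSet(kind="deceleration", times=times,
                             peak_values=peaks, peak_times=times + 0.1)
        ratios = []
        for gain in (1.0, 2.0, 4.0):
            amps = 10.0 * (1.0 + (gain - 1.0)
                           * (np.abs(peaks) - 2.0) / 2.5)
            trace = kernel_trace(n, ((times + 0.3) * 100).astype(int), amps)
            q = quintile_analysis(events, trace)
            ratios.append(q.ratio)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_too_few_events_raises(self):
        events = pl.EventSet("deceleration", np.array([1.0]),
                             np.array([-3.0]), np.array([1.1]))
        with pytest.raises(InsufficientDataError):
            quintile_analysis(events, np.zeros(1000))


class TestVelocityTuning:
    def test_dff_equal_to_velocity_recovers_bin_means(self, rng):
        v = rng.uniform(-0.05, 1.0, 50000)
        edges, means = velocity_tuning(v, v)
        for b in range(edges.size - 1):
            sel = (v > edges[b]) & (v <= edges[b + 1]) if False else \
                (np.digitize(v, edges) - 1 == b)
            if sel.any():
                assert means[b] == pytest.approx(v[sel].mean(), abs=1e-9)

    def test_all_velocity_in_one_bin_others_missing(self):
        v = np.full(1000, 0.32)
        edges, means = velocity_tuning(np.ones(1000), v)
        assert np.isfinite(means).sum() == 1

    def test_flat_relationship_is_flat(self, rng):
        v = rng.uniform(0.0, 0.7, 50000)
        dff = rng.normal(5.0, 1.0, 50000)
        _, means = velocity_tuning(dff, v)
        good = np.isfinite(means)
        assert np.nanstd(means[good]) < 0.2
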