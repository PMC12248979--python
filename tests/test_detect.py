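"""Microsaccade detector: velocity estimation, thresholds, event filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fixfill.detect import (
    DetectionParams,
    Microsaccade,
    VelocitySeries,
    compute_velocity,
    detect_microsaccades,
    estimate_threshold,
    main_sequence,
    merge_events,
)
from fixfill.gaze import GazeTrace
from fixfill.synth import InjectedEvent, SimConfig, generate_trace


def make_trace(pos: np.ndarray, fs: float = 1000.0, valid=None) -> GazeTrace:
    n = len(pos)
    valid = np.ones(n, dtype=bool) if valid is None else valid
    return GazeTrace(
        time_ms=np.arange(n) * 1000.0 / fs,
        left=pos.copy(), right=pos.copy(),
        valid_left=valid.copy(), valid_right=valid.copy(),
        sampling_rate=fs,
    )


class TestComputeVelocity:
    def test_constant_position_zero_velocity(self):
        tr = make_trace(np.full((500, 2), 0.3))
        v = compute_velocity(tr)
        assert np.nanmax(np.abs(v.left)) < 1e-12

    def test_linear_ramp_recovers_slope(self):
        t = np.arange(500) / 1000.0
        pos = np.column_stack([3.0 * t, -1.5 * t])
        v = compute_velocity(make_trace(pos))
        d = v.defined
        np.testing.assert_allclose(v.left[d, 0], 3.0, atol=1e-9)
        np.testing.assert_allclose(v.right[d, 1], -1.5, atol=1e-9)

    def test_matches_brute_force_windowed_regression(self, rng):
        """Oracle: per-window least-squares slope computed sample by sample."""
        pos = np.cumsum(rng.normal(0, 0.001, (300, 2)), axis=0)
        tr = make_trace(pos)
        v = compute_velocity(tr, window_ms=31.0)
        k = 15
        x = np.arange(-k, k + 1)
        for n in np.where(v.defined)[0][::17]:
            for ax in range(2):
                slope = np.polyfit(x / 1000.0, pos[n - k:n + k + 1, ax], 1)[0]
                assert v.left[n, ax] == pytest.approx(slope, rel=1e-9, abs=1e-12)

    def test_blink_neighbourhood_undefined(self):
        valid = np.ones(2000, dtype=bool)
        valid[900:1000] = False
        tr = make_trace(np.zeros((2000, 2)), valid=valid)
        v = compute_velocity(tr, blink_pad_ms=150.0)
        # pad 150 ms + half window on each side of the invalid run
        assert not v.defined[900 - 150 - 15:1000 + 150 + 15].any()
        assert v.defined[500] and v.defined[1400]

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_velocity(make_trace(np.zeros((20, 2))))


class TestEstimateThreshold:
    def _series(self, v: np.ndarray) -> VelocitySeries:
        n = len(v)
        return VelocitySeries(time_ms=np.arange(n, dtype=float), left=v,
                              right=v.copy(), defined=np.ones(n, dtype=bool))

    def test_gaussian_noise_gives_robust_sd(self, rng):
        """For v ~ N(0, s^2) the median-based scale is 0.6745 s."""
        s = 2.3
        v = rng.normal(0, s, (200_000, 2))
        eta = estimate_threshold(self._series(v), noise_multiplier=5.0)
        np.testing.assert_allclose(eta, 5 * 0.6745 * s, rtol=0.02)

    def test_multiplier_override_scales_linearly(self, rng):
        v = rng.normal(0, 1.0, (5000, 2))
        e5 = estimate_threshold(self._series(v), 5.0)
        e6 = estimate_threshold(self._series(v), 6.0)
        np.testing.assert_allclose(e6, e5 * 6 / 5)

    def test_degenerate_constant_velocity_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_threshold(self._series(np.zeros((500, 2))))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            estimate_threshold(self._series(rng.normal(size=(50, 2))))


class TestDetectMicrosaccades:
    def test_single_injected_event_detected_once(self):
        cfg = SimConfig(drift_diffusion=1e-4, noise_sd=0.1, blink_rate=0.0)
        tr = generate_trace(5.0, [InjectedEvent(2.0, 0.5, 30.0)], [], cfg, seed=1)
        micro, large = detect_microsaccades(tr)
        assert len(micro) == 1 and len(large) == 0
        # the 31-ms centred window anticipates the true onset slightly
        assert abs(micro[0].onset_ms - 2000.0) <= 10.0
        assert micro[0].amplitude_deg == pytest.approx(0.5, rel=0.2)

    def test_close_events_merged(self):
        """Two ballistic events separated by ~10 ms count as one."""
        cfg = SimConfig(drift_diffusion=1e-4, noise_sd=0.1, blink_rate=0.0)
        T = cfg.saccade_duration_s
        evs = [InjectedEvent(2.0, 0.4, 0.0), InjectedEvent(2.0 + T + 0.010, 0.4, 0.0)]
        tr = generate_trace(5.0, evs, [], cfg, seed=2)
        micro, large = detect_microsaccades(tr)
        assert len(micro) + len(large) == 1

    def test_tiny_event_classified_as_drift(self):
        cfg = SimConfig(drift_diffusion=1e-4, noise_sd=0.1, blink_rate=0.0)
        tr = generate_trace(5.0, [InjectedEvent(2.0, 2.0 / 60.0, 0.0)], [], cfg, seed=3)
        micro, _ = detect_microsaccades(tr)
        assert micro == []

    def test_large_saccade_reported_separately(self):
        cfg = SimConfig(drift_diffusion=1e-4, noise_sd=0.1, blink_rate=0.0,
                        amp_bounds_arcmin=(3.0, 200.0))
        tr = generate_trace(5.0, [InjectedEvent(2.0, 2.5, 0.0)], [], cfg, seed=4)
        micro, large = detect_microsaccades(tr)
        assert len(large) == 1 and micro == []
        assert large[0].amplitude_deg > 2.0

    def test_no_event_touches_blink_pad(self):
        """Events overlapping the padded blink region are impossible."""
        cfg = SimConfig(drift_diffusion=1e-4, noise_sd=0.1, blink_rate=0.0)
        evs = [InjectedEvent(2.3, 0.5, 0.0)]  # 150-ms pad after blink covers it
        tr = generate_trace(5.0, evs, [(2.0, 2.25)], cfg, seed=5)
        micro, large = detect_microsaccades(tr)
        for ev in micro + large:
            assert ev.offset_ms < 2000 - 150 or ev.onset_ms > 2250 + 150

    def test_output_respects_amplitude_and_duration_bounds(self, small_experiment):
        cfg, trials, traces, truth = small_experiment
        params = DetectionParams()
        for tid in trials["trial_id"]:
            micro, _ = detect_microsaccades(traces[tid], params)
            for ev in micro:
                assert params.amp_min_arcmin / 60.0 <= ev.amplitude_deg <= params.amp_max_deg
                assert ev.duration_ms >= (params.min_duration_samples - 1)
                assert ev.peak_velocity > 0

    def test_recall_and_amplitude_accuracy(self, small_experiment):
        """Injected events of >= 6 arcmin are recovered with faithful amplitude."""
        cfg, trials, traces, truth = small_experiment
        found, total, amp_err = 0, 0, []
        for tid in trials["trial_id"]:
            micro, large = detect_microsaccades(traces[tid])
            det = micro + large
            for ev in truth.injected_events[tid]:
                if ev.amplitude_deg < 6.0 / 60.0:
                    continue
                total += 1
                onset = ev.onset_s * 1000.0
                hits = [d for d in det if abs(d.onset_ms - onset) < 20.0]
                if hits:
                    found += 1
                    amp_err.append(abs(hits[0].amplitude_deg - ev.amplitude_deg)
                                   / ev.amplitude_deg)
        assert total >= 50
        assert found / total >= 0.9
        assert np.median(amp_err) <= 0.2

    def test_false_alarm_rate_on_pure_drift(self):
        """No injected events: spurious detections under 0.05 Hz over >=100 s."""
        cfg = SimConfig(blink_rate=0.0)
        n_events, total_s = 0, 0.0
        for s in range(12):
            tr = generate_trace(10.0, [], [], cfg, seed=1000 + s)
            micro, large = detect_microsaccades(tr)
            n_events += len(micro) + len(large)
            total_s += 10.0
        assert total_s >= 100.0
        assert n_events / total_s < 0.05


class TestMergeEvents:
    def test_gap_below_threshold_merges(self):
        assert merge_events([(0, 10), (15, 30)], 12) == [(0, 30)]
        assert merge_events([(0, 10), (30, 40)], 12) == [(0, 10), (30, 40)]

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 40)), max_size=12),
           st.floats(1.0, 20.0))
    @settings(deadline=None, max_examples=60)
    def test_merging_is_idempotent(self, raw, gap):
        runs = sorted((s, s + d) for s, d in raw)
        once = merge_events(runs, gap)
        assert merge_events(once, gap) == once


class TestMainSequence:
    def test_exact_proportionality(self):
        evs = [Microsaccade(0, 10, a, 60.0 * a, 0.0) for a in np.linspace(0.1, 1.0, 12)]
        slope, r = main_sequence(evs)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_detected_events_conform(self, small_experiment):
        cfg, trials, traces, _ = small_experiment
        events = []
        for tid in trials["trial_id"]:
            micro, _ = detect_microsaccades(traces[tid])
            events.extend(micro)
        assert len(events) >= 50
        _, r = main_sequence(events)
        assert r > 0.9

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="10"):
            main_sequence([Microsaccade(0, 10, 0.2, 12.0, 0.0)])
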