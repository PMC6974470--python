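"""Relative-difference step registration: each gate of the criteria chain."""

import warnings

import numpy as np
import pytest

from tokeda.conditioning import Envelope
from tokeda.config import StepDetectionParams
from tokeda.step_detection import (
    RelativeDifference,
    StepEvent,
    activity_metrics,
    detect_steps,
    normalize_pair,
    relative_difference,
    step_cycle_window,
)
from tokeda.thresholding import BurstInterval

RATE = 1000.0


class TestNormalizePair:
    def test_peak_maps_to_one(self):
        ta = Envelope(np.array([0.0, 1.0, 2.0, 0.5]), RATE)
        sol = Envelope(np.array([0.0, 4.0, 1.0, 0.0]), RATE)
        ta_n, sol_n = normalize_pair(ta, sol)
        assert ta_n.max() == 1.0 and sol_n.max() == 1.0
        assert ta_n[2] == 1.0

    def test_all_zero_channel_stays_zero(self):
        ta = Envelope(np.zeros(10), RATE)
        sol = Envelope(np.ones(10), RATE)
        ta_n, _ = normalize_pair(ta, sol)
        np.testing.assert_array_equal(ta_n, 0.0)

    def test_joint_scaling_is_invisible(self, rng):
        a, b = np.abs(rng.standard_normal(100)), np.abs(rng.standard_normal(100))
        base = normalize_pair(Envelope(a, RATE), Envelope(b, RATE))
        scaled = normalize_pair(Envelope(7.3 * a, RATE), Envelope(7.3 * b, RATE))
        np.testing.assert_allclose(scaled[0], base[0])
        np.testing.assert_allclose(scaled[1], base[1])


class TestRelativeDifference:
    @pytest.mark.parametrize("ta,sol,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0)])
    def test_pointwise_difference(self, ta, sol, expected):
        d = relative_difference(np.full(5, ta), np.full(5, sol), "L", RATE)
        np.testing.assert_allclose(d.values, expected)
        assert np.all(np.abs(d.values) <= 1.0)


def make_diff(
    peaks=((1.0, 0.5),),
    t_neg=1.2,
    neg_amp=0.3,
    baseline=0.005,
    dur=3.0,
    rate=RATE,
    side="L",
):
    """Difference trace: positive Gaussian flexion lobes on a small positive
    baseline, followed by one negative extension lobe."""
    t = np.arange(int(dur * rate)) / rate
    v = np.full(t.size, baseline)
    for tp, amp in peaks:
        v += amp * np.exp(-0.5 * ((t - tp) / 0.04) ** 2)
    v -= neg_amp * np.exp(-0.5 * ((t - t_neg) / 0.06) ** 2)
    return RelativeDifference(v, rate, side)


TA_BURST = [BurstInterval(0.8, 1.5)]
SOL_BURST = [BurstInterval(1.05, 2.05)]  # 1 s, qualifying


class TestDetectStepsGates:
    def test_reference_waveform_registers_one_step(self):
        events = detect_steps(make_diff(), TA_BURST, SOL_BURST)
        assert len(events) == 1
        e = events[0]
        assert e.peak_time_s == pytest.approx(1.0, abs=0.01)
        assert 1.0 < e.zero_cross_s <= 1.2
        e.check()

    def test_gate_positive_peak(self):
        """A negative-going lobe offers no positive local maximum."""
        d = make_diff(peaks=((1.0, -0.5),), baseline=0.0)
        assert detect_steps(d, TA_BURST, SOL_BURST) == []

    def test_gate_inside_ta_burst(self):
        """The same peak outside any flexor burst is ignored."""
        ta_elsewhere = [BurstInterval(2.0, 2.5)]
        assert detect_steps(make_diff(), ta_elsewhere, SOL_BURST) == []
        assert detect_steps(make_diff(), [], SOL_BURST) == []

    def test_gate_magnitude_threshold(self):
        """A 0.005 peak sits below the 0.01 difference threshold."""
        d = make_diff(peaks=((1.0, 0.005),), baseline=0.0, neg_amp=0.3)
        assert detect_steps(d, TA_BURST, SOL_BURST) == []
        d_ok = make_diff(peaks=((1.0, 0.05),))
        assert len(detect_steps(d_ok, TA_BURST, SOL_BURST)) == 1

    def test_gate_negative_within_follow_window(self):
        """Extension starting 0.8 s after the peak misses the 0.5 s window."""
        d = make_diff(t_neg=1.8)
        sol = [BurstInterval(1.5, 2.8)]
        assert detect_steps(d, TA_BURST, sol) == []
        # same geometry, extension at 1.2 s: accepted
        assert len(detect_steps(make_diff(t_neg=1.2), TA_BURST, sol + SOL_BURST)) == 1

    def test_gate_sol_burst_duration(self):
        """A 0.2 s extensor burst (< 0.25 s) cannot confirm the step."""
        short_sol = [BurstInterval(1.05, 1.25)]
        assert detect_steps(make_diff(), TA_BURST, short_sol) == []
        long_sol = [BurstInterval(1.05, 1.35)]  # 0.30 s >= 0.25 s
        assert len(detect_steps(make_diff(), TA_BURST, long_sol)) == 1

    def test_gate_last_maximum_in_burst(self):
        """Two well-separated peaks in one flexor burst: the last one wins."""
        d = make_diff(peaks=((1.0, 0.4), (1.35, 0.5)), t_neg=1.55)
        events = detect_steps(d, TA_BURST, [BurstInterval(1.4, 2.4)])
        assert len(events) == 1
        assert events[0].peak_time_s == pytest.approx(1.35, abs=0.01)

    def test_gate_peak_separation(self):
        """Candidates closer than 0.2 s to the previous accepted candidate
        are dropped, so the earlier of two crowded peaks is the survivor."""
        d = make_diff(peaks=((1.0, 0.5), (1.1, 0.4)), t_neg=1.3)
        events = detect_steps(d, TA_BURST, SOL_BURST)
        assert len(events) == 1
        assert events[0].peak_time_s == pytest.approx(1.0, abs=0.01)

    def test_at_most_one_event_per_ta_burst(self):
        d = make_diff(peaks=((1.0, 0.5), (1.3, 0.45)), t_neg=1.5)
        events = detect_steps(d, TA_BURST, [BurstInterval(1.35, 2.4)])
        assert len(events) == 1

    def test_raising_diff_threshold_never_adds_events(self):
        d = make_diff(peaks=((1.0, 0.3),))
        counts = []
        for thr in (0.01, 0.2, 0.5):
            p = StepDetectionParams(diff_threshold=thr)
            counts.append(len(detect_steps(d, TA_BURST, SOL_BURST, p)))
        assert counts == sorted(counts, reverse=True)

    def test_events_satisfy_ordering_invariant(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # positive baseline clamps swing onset
            for e in detect_steps(make_diff(), TA_BURST, SOL_BURST):
                full = step_cycle_window(make_diff(), e, SOL_BURST)
                assert full.swing_start_s <= full.peak_time_s < full.zero_cross_s <= full.stance_end_s


class TestStepCycleWindow:
    def _sine_diff(self):
        t = np.arange(int(4 * RATE)) / RATE
        return RelativeDifference(0.5 * np.sin(2 * np.pi * 0.5 * t), RATE, "L")

    def test_sine_wave_uses_adjacent_zero_crossings(self):
        d = self._sine_diff()
        e = StepEvent("L", peak_time_s=0.5, zero_cross_s=1.001)
        out = step_cycle_window(d, e, [BurstInterval(1.0, 2.5)])
        assert out.swing_start_s == pytest.approx(0.0, abs=2 / RATE)
        assert out.stance_end_s == pytest.approx(2.0, abs=2 / RATE)

    def test_sol_burst_ending_early_caps_stance(self):
        d = self._sine_diff()
        e = StepEvent("L", peak_time_s=0.5, zero_cross_s=1.001)
        out = step_cycle_window(d, e, [BurstInterval(1.0, 1.5)])
        assert out.stance_end_s == pytest.approx(1.5)

    def test_positive_from_start_clamps_with_warning(self):
        t = np.arange(int(2 * RATE)) / RATE
        v = 0.2 + 0.3 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        v[int(0.8 * RATE) :] = -0.1
        d = RelativeDifference(v, RATE, "L")
        e = StepEvent("L", peak_time_s=0.5, zero_cross_s=0.8)
        with pytest.warns(UserWarning, match="clamped"):
            out = step_cycle_window(d, e, [BurstInterval(0.8, 1.8)])
        assert out.swing_start_s == pytest.approx(0.0)


class TestActivityMetrics:
    def _events(self, n, spacing_s=30.0, stance=2.0):
        out = []
        for k in range(n):
            t = 1.0 + k * spacing_s
            out.append(StepEvent("L", t, t + 0.2, swing_start_s=t - 0.2, stance_end_s=t + 0.2 + stance))
        return out

    def test_twelve_events_in_six_minutes(self):
        m = activity_metrics(self._events(12), {}, segment_length_s=360.0)
        assert m.mean_steps_per_min == pytest.approx(2.0)
        assert m.steps_per_min.sum() == 12

    def test_stance_periods(self):
        m = activity_metrics(self._events(5, stance=1.5), {}, 360.0)
        np.testing.assert_allclose(m.stance_periods_s, 1.5)
        assert m.mean_stance_s == pytest.approx(1.5)

    def test_percent_change_vs_reference(self):
        m = activity_metrics(self._events(150, spacing_s=2.0), {}, 360.0, reference_step_count=50)
        assert m.percent_change_steps == pytest.approx(300.0)

    def test_zero_reference_reported_missing(self):
        m = activity_metrics(self._events(3), {}, 360.0, reference_step_count=0)
        assert m.percent_change_steps is None

    def test_constant_envelope_gives_linear_cumulative_iemg(self):
        env = Envelope(np.ones(1000), RATE)
        m = activity_metrics([], {"LTA": env}, 1.0, iemg_points=50)
        c = m.cumulative_iemg["LTA"]
        assert c[0] == pytest.approx(0.0)
        assert c[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(c, np.linspace(0, 1, 50), atol=0.005)
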