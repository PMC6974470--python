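"""Rest-period discovery and the double (magnitude + duration) threshold."""

import numpy as np
import pytest

from oracles import burst_scan_oracle
from tokeda.conditioning import Envelope
from tokeda.config import ThresholdingParams
from tokeda.thresholding import (
    BurstThreshold,
    RestSegment,
    compute_bin_thresholds,
    compute_threshold,
    detect_bursts,
    find_rest_period,
)

RATE = 1000.0


def _env(values, rate=RATE):
    return Envelope(np.asarray(values, dtype=float), rate)


class TestFindRestPeriod:
    def test_flat_envelope_rest_is_entire_bin(self, flat_envelope):
        rest = find_rest_period(flat_envelope, 0.0, 10.0)
        assert rest.start_s == pytest.approx(0.0)
        assert rest.end_s == pytest.approx(10.0)
        assert rest.mu_rest == pytest.approx(0.01)
        assert rest.sigma_rest == 0.0

    def test_mid_bin_burst_is_excluded(self):
        v = np.full(10_000, 0.01)
        v[4000:5000] = 1.0  # 1 s burst mid-bin
        rest = find_rest_period(_env(v), 0.0, 10.0)
        assert rest.mu_rest == pytest.approx(0.01, rel=1e-9)
        # exhaustive check: no burst sample inside the grown window
        a, b = int(rest.start_s * RATE), int(rest.end_s * RATE)
        assert v[a:b].max() == pytest.approx(0.01)

    def test_growth_stops_at_plateau_step(self):
        v = np.concatenate([np.full(5000, 0.01), np.full(5000, 0.2)])
        rest = find_rest_period(_env(v), 0.0, 10.0)
        # seed lands in the lower plateau; the step differential
        # (19 rest floors per 10 ms block = 1900/s) exceeds dmax = 1000/s
        assert rest.end_s <= 5.0 + 0.011
        assert rest.mu_rest == pytest.approx(0.01, rel=1e-6)

    def test_growth_matches_brute_force_simulation(self, rng):
        """Grown window equals a step-by-step simulation of the same rules."""
        p = ThresholdingParams()
        for _ in range(10):
            v = np.abs(rng.standard_normal(10_000) * 0.005) + 0.01
            v[rng.integers(0, 9000) : :][:1000] += rng.uniform(0.5, 2.0)
            env = _env(v)
            rest = find_rest_period(env, 0.0, 10.0, p)
            means = v[:10_000].reshape(1000, 10).mean(axis=1)
            seed = int(np.argmin(means))
            lo = hi = seed
            log_sum = 0.0
            block_dur = 10 / RATE

            def cost(m):
                return np.log1p(max(0.0, m - means[seed]) / means[seed])

            while True:
                grew = False
                if hi + 1 < 1000:
                    c = cost(means[hi + 1])
                    if (
                        abs(means[hi + 1] - means[hi]) / (block_dur * means[seed])
                        <= p.dmax
                        and log_sum + c <= p.log_thresh
                    ):
                        hi += 1
                        log_sum += c
                        grew = True
                if lo - 1 >= 0:
                    c = cost(means[lo - 1])
                    if (
                        abs(means[lo - 1] - means[lo]) / (block_dur * means[seed])
                        <= p.dmax
                        and log_sum + c <= p.log_thresh
                    ):
                        lo -= 1
                        log_sum += c
                        grew = True
                if not grew:
                    break
            assert rest.start_s == pytest.approx(lo * 10 / RATE)
            assert rest.end_s == pytest.approx((hi + 1) * 10 / RATE)

    def test_bin_shorter_than_two_blocks_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            find_rest_period(_env(np.zeros(100)), 0.0, 0.015)


class TestComputeThreshold:
    @pytest.mark.parametrize(
        "mu,sigma,expected",
        [(0.10, 0.02, 0.24), (0.5, 0.0, 0.5), (0.0, 1.0, 7.0)],
    )
    def test_magnitude_formula(self, mu, sigma, expected):
        rest = RestSegment(0, 0.0, 10.0, mu, sigma)
        thr = compute_threshold(rest, "TA")
        assert thr.magnitude == pytest.approx(expected)

    def test_channel_duration_criteria(self):
        rest = RestSegment(0, 0.0, 10.0, 0.1, 0.01)
        assert compute_threshold(rest, "TA").min_duration_s == 0.1
        assert compute_threshold(rest, "Sol").min_duration_s == 0.3

    def test_nonpositive_j_rejected(self):
        rest = RestSegment(0, 0.0, 10.0, 0.1, 0.01)
        with pytest.raises(ValueError, match="J"):
            compute_threshold(rest, "TA", j_scale=0.0)


def _thr(mag, min_dur, start, end):
    return BurstThreshold(0, mag, min_dur, start_s=start, end_s=end)


class TestDetectBursts:
    def test_flat_below_threshold_no_bursts(self, flat_envelope):
        assert detect_bursts(flat_envelope, [_thr(0.5, 0.1, 0.0, 10.0)]) == []

    def test_half_second_ta_plateau_accepted(self):
        v = np.full(10_000, 0.01)
        v[2000:2500] = 1.0
        bursts = detect_bursts(_env(v), [_thr(0.5, 0.1, 0.0, 10.0)])
        assert len(bursts) == 1
        assert bursts[0].start_s == pytest.approx(2.0)
        assert bursts[0].duration_s == pytest.approx(0.5)

    def test_sol_plateau_meets_magnitude_but_not_time(self):
        """0.2 s supra-threshold activity on an extensor channel (minimum
        0.3 s) is not a burst: the double threshold's time criterion."""
        v = np.full(10_000, 0.01)
        v[2000:2200] = 1.0
        assert detect_bursts(_env(v), [_thr(0.5, 0.3, 0.0, 10.0)]) == []

    def test_burst_crossing_bin_boundary_is_one_union_run(self):
        v = np.full(20_000, 0.01)
        v[9800:10_300] = 1.0  # 0.5 s spanning the 10 s bin edge
        thrs = [_thr(0.5, 0.3, 0.0, 10.0), _thr(0.5, 0.3, 10.0, 20.0)]
        bursts = detect_bursts(_env(v), thrs)
        assert len(bursts) == 1
        assert bursts[0].duration_s == pytest.approx(0.5)

    def test_matches_exhaustive_per_sample_scan(self, rng):
        for _ in range(10):
            v = np.abs(rng.standard_normal(20_000)) * 0.1
            thrs = [
                _thr(rng.uniform(0.05, 0.3), 0.01, 0.0, 10.0),
                _thr(rng.uniform(0.05, 0.3), 0.01, 10.0, 20.0),
            ]
            env = _env(v)
            got = [(b.start_s, b.end_s) for b in detect_bursts(env, thrs)]
            per_sample = np.where(np.arange(20_000) < 10_000, thrs[0].magnitude, thrs[1].magnitude)
            expected = burst_scan_oracle(v, per_sample, RATE, 0.01)
            assert got == pytest.approx(expected)

    def test_monotonic_in_j(self, rng):
        """The set of burst samples never grows as J increases."""
        v = np.abs(rng.standard_normal(10_000)) * 0.1 + 0.01
        env = _env(v)
        rest = find_rest_period(env, 0.0, 10.0)
        prev = None
        for j in (3.0, 5.0, 7.0, 9.0):
            thr = compute_threshold(rest, "TA", j_scale=j)
            thr.start_s, thr.end_s = 0.0, 10.0
            mask = np.zeros(10_000, dtype=bool)
            for b in detect_bursts(env, [thr]):
                mask[int(b.start_s * RATE) : int(b.end_s * RATE)] = True
            if prev is not None:
                assert not (mask & ~prev).any()  # subset of previous
            prev = mask

    def test_positive_scale_invariance(self, rng):
        v = np.abs(rng.standard_normal(10_000)) * 0.1 + 0.01
        env = _env(v)
        rest = find_rest_period(env, 0.0, 10.0)
        thr = compute_threshold(rest, "TA")
        thr.start_s, thr.end_s = 0.0, 10.0
        base = [(b.start_s, b.end_s) for b in detect_bursts(env, [thr])]
        for k in (0.1, 3.7, 100.0):
            env_k = _env(k * v)
            rest_k = find_rest_period(env_k, 0.0, 10.0)
            assert rest_k.mu_rest == pytest.approx(k * rest.mu_rest)
            assert rest_k.sigma_rest == pytest.approx(k * rest.sigma_rest)
            thr_k = compute_threshold(rest_k, "TA")
            assert thr_k.magnitude == pytest.approx(k * thr.magnitude)
            thr_k.start_s, thr_k.end_s = 0.0, 10.0
            got = [(b.start_s, b.end_s) for b in detect_bursts(env_k, [thr_k])]
            assert got == pytest.approx(base)

    def test_burst_invariants_hold(self, rng):
        v = np.abs(rng.standard_normal(10_000)) * 0.1
        env = _env(v)
        thr = _thr(0.15, 0.01, 0.0, 10.0)
        for b in detect_bursts(env, [thr]):
            assert b.duration_s >= 0.01
            a, e = int(b.start_s * RATE), int(b.end_s * RATE)
            assert (v[a:e] >= 0.15).all()


class TestBinThresholds:
    def test_short_trailing_bin_inherits_previous_threshold(self, rng):
        v = np.abs(rng.standard_normal(11_000)) * 0.05  # 10 s + 1 s partial
        thrs = compute_bin_thresholds(_env(v), "TA")
        assert len(thrs) == 2
        assert thrs[1].magnitude == thrs[0].magnitude
        assert thrs[1].end_s == pytest.approx(11.0)

    def test_long_trailing_bin_is_processed(self, rng):
        v = np.abs(rng.standard_normal(13_000)) * 0.05  # 10 s + 3 s partial
        thrs = compute_bin_thresholds(_env(v), "TA")
        assert len(thrs) == 2
        assert thrs[1].magnitude != thrs[0].magnitude
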