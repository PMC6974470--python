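"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive implementations (explicit loops, textbook definitions)
kept free of any code from the package's own detection paths.
"""

import numpy as np


def burst_scan_oracle(values, thresholds, rate, min_duration_s, t0=0.0):
    """Exhaustive per-sample burst scan.

    ``thresholds`` is a per-sample array of magnitude thresholds. Returns
    [start_s, end_s) pairs of maximal supra-threshold runs that meet the
    duration criterion.
    """
    runs = []
    in_run = False
    start = 0
    for i, (v, thr) in enumerate(zip(values, thresholds)):
        if v >= thr and not in_run:
            in_run, start = True, i
        elif v < thr and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(values)))
    return [
        (t0 + s / rate, t0 + e / rate)
        for s, e in runs
        if (e - s) / rate >= min_duration_s
    ]


def _prominence(y, i):
    """Topographic prominence of the local maximum at index i."""
    left_min = y[i]
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        left_min = min(left_min, y[j])
        j -= 1
    if j >= 0:  # a higher point exists to the left
        base_left = left_min
    else:
        base_left = left_min
    right_min = y[i]
    j = i + 1
    while j < y.size and y[j] <= y[i]:
        right_min = min(right_min, y[j])
        j += 1
    base_right = right_min
    return y[i] - max(base_left, base_right)


def extrema_oracle(y, dt, min_separation_s, min_prominence, d2_threshold):
    """Brute-force filtered extremum enumeration on an interpolated trace.

    Mirrors the detection contract from first principles: (1) all strict
    local maxima; (2) minimum-separation filter, keeping taller extrema
    first; (3) topographic-prominence floor; (4) absolute second-differential
    floor via central differences. Returns (peak_indices, trough_indices).
    """

    def one_sign(sig):
        z = sig * y
        cand = [
            i
            for i in range(1, z.size - 1)
            if z[i] > z[i - 1] and z[i] > z[i + 1]
        ]
        # separation: greedy from the tallest
        min_gap = int(np.ceil(min_separation_s / dt))
        kept: list[int] = []
        for i in sorted(cand, key=lambda i: z[i], reverse=True):
            if all(abs(i - k) >= min_gap for k in kept):
                kept.append(i)
        kept = sorted(kept)
        # prominence on the full trace
        kept = [i for i in kept if _prominence(z, i) >= min_prominence]
        # curvature floor
        out = []
        for i in kept:
            d2 = (y[i + 1] - 2 * y[i] + y[i - 1]) / dt**2
            if abs(d2) >= d2_threshold:
                out.append(i)
        return out

    return one_sign(+1.0), one_sign(-1.0)


def optimal_match_count(detected_intervals, annotated_intervals, tolerance_s):
    """Maximum-cardinality detection/annotation matching by brute force.

    Events are (a, b, zero_cross/onset) tuples; compatibility is interval
    overlap or |zero_cross - onset| <= tolerance. Exhaustive recursion,
    only viable for ~10 events.
    """

    def compatible(d, a):
        overlap = a[0] < d[1] and d[0] < a[1]
        close = abs(d[2] - a[2]) <= tolerance_s
        return overlap or close

    def best(di, used):
        if di == len(detected_intervals):
            return 0
        score = best(di + 1, used)  # leave this detection unmatched
        for ai, a in enumerate(annotated_intervals):
            if ai not in used and compatible(detected_intervals[di], a):
                score = max(score, 1 + best(di + 1, used | {ai}))
        return score

    return best(0, frozenset())
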