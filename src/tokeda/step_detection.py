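"""Step-like event detection from flexor/extensor coordination.

The TA (flexor) and Sol (extensor) envelopes are each normalized to their
own maximum over the processing segment and subtracted, giving a relative
difference signal in [-1, 1]: positive means net ankle flexion, negative
net extension. A step-like event is a positive flexion peak, inside an
active TA burst, that is followed within 0.5 s by a negative phase
overlapping a sufficiently long active Sol burst — the signature of a
swing-to-stance transition. Candidate peaks must clear a magnitude floor
and a minimum inter-peak spacing, and only the last qualifying maximum
within each TA burst is kept, so each flexor burst yields at most one step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, integrate

from .config import StepDetectionParams
from .conditioning import Envelope
from .thresholding import BurstInterval

__all__ = [
    "RelativeDifference",
    "StepEvent",
    "normalize_pair",
    "relative_difference",
    "detect_steps",
    "step_cycle_window",
    "activity_metrics",
    "ActivityMetrics",
    "events_to_frame",
]


@dataclass
class RelativeDifference:
    """Normalized TA minus normalized Sol; bounded in [-1, 1]."""

    values: np.ndarray
    rate: float
    side: str
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return self.values.size

    def time_to_index(self, t_s: float) -> int:
        return int(round((t_s - self.t0) * self.rate))

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.rate


@dataclass
class StepEvent:
    """One detected step-like event on one limb.

    ``peak_time_s`` is the flexion maximum of the difference signal,
    ``zero_cross_s`` the flexion-to-extension transition; the full cycle
    spans ``swing_start_s`` to ``stance_end_s`` once delimited.
    """

    side: str
    peak_time_s: float
    zero_cross_s: float
    swing_start_s: Optional[float] = None
    stance_end_s: Optional[float] = None

    @property
    def stance_period_s(self) -> Optional[float]:
        if self.stance_end_s is None:
            return None
        return self.stance_end_s - self.zero_cross_s

    def check(self) -> None:
        if not self.peak_time_s < self.zero_cross_s:
            raise ValueError("peak must precede the zero crossing")
        if self.swing_start_s is not None and self.swing_start_s > self.peak_time_s:
            raise ValueError("swing start must not follow the peak")
        if self.stance_end_s is not None and self.stance_end_s < self.zero_cross_s:
            raise ValueError("stance end must not precede the zero crossing")


def normalize_pair(
    ta_env: Envelope, sol_env: Envelope
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each envelope by its own maximum over the current segment.

    Compensates for unknown per-channel gain (no force calibration exists
    for chronic intramuscular electrodes). An all-zero channel maps to
    all zeros rather than dividing by zero.
    """
    if len(ta_env) != len(sol_env):
        raise ValueError("TA and Sol envelopes must be the same length")
    if ta_env.rate != sol_env.rate:
        raise ValueError("TA and Sol envelopes must share a sampling rate")

    def norm(v: np.ndarray) -> np.ndarray:
        m = v.max() if v.size else 0.0
        return v / m if m > 0 else np.zeros_like(v)

    return norm(ta_env.values), norm(sol_env.values)


def relative_difference(
    ta_norm: np.ndarray,
    sol_norm: np.ndarray,
    side: str,
    rate: float,
    t0: float = 0.0,
) -> RelativeDifference:
    """Pointwise normalized TA - Sol (positive = net flexion)."""
    ta_norm = np.asarray(ta_norm, dtype=float)
    sol_norm = np.asarray(sol_norm, dtype=float)
    if ta_norm.shape != sol_norm.shape:
        raise ValueError("normalized channels must have equal length")
    return RelativeDifference(ta_norm - sol_norm, rate, side, t0)


def _interval_index(bursts: list[BurstInterval], t_s: float) -> Optional[int]:
    for k, b in enumerate(bursts):
        if b.contains(t_s):
            return k
    return None


def detect_steps(
    diff: RelativeDifference,
    ta_bursts: list[BurstInterval],
    sol_bursts: list[BurstInterval],
    params: Optional[StepDetectionParams] = None,
) -> list[StepEvent]:
    """Register step-like events from the relative-difference signal.

    Candidate peaks are local maxima of the difference that are (a)
    positive, (b) inside an active TA burst, (c) above ``diff_threshold``,
    and (d) at least ``peak_separation_s`` after the previously accepted
    candidate; within each TA burst only the last surviving candidate is
    considered. The candidate becomes a step iff the difference turns
    negative within ``follow_window_s`` of the peak and that negative phase
    overlaps a Sol burst lasting at least ``sol_burst_min_s``.
    """
    p = params or StepDetectionParams()
    v = diff.values
    if v.size < 3 or not ta_bursts:
        return []
    peak_idx, _ = signal.find_peaks(v)

    # gates (a)-(c), then the candidate-level separation rule (d)
    min_sep = p.peak_separation_s
    accepted: list[tuple[int, int]] = []  # (sample index, TA-burst index)
    last_t = -np.inf
    for i in peak_idx:
        if v[i] <= 0 or v[i] <= p.diff_threshold:
            continue
        t = diff.index_to_time(int(i))
        k = _interval_index(ta_bursts, t)
        if k is None:
            continue
        if t - last_t < min_sep:
            continue
        accepted.append((int(i), k))
        last_t = t

    # one candidate per TA burst: keep the last
    last_in_burst: dict[int, int] = {}
    for i, k in accepted:
        last_in_burst[k] = i

    qualifying_sols = [b for b in sol_bursts if b.duration_s >= p.sol_burst_min_s]
    events: list[StepEvent] = []
    follow = int(round(p.follow_window_s * diff.rate))
    for k in sorted(last_in_burst):
        i = last_in_burst[k]
        seg = v[i + 1 : i + 1 + follow]
        neg = np.flatnonzero(seg < 0)
        if neg.size == 0:
            continue
        j0 = i + 1 + int(neg[0])  # first negative sample after the peak
        # extent of the contiguous negative phase
        rest = v[j0:]
        nonneg = np.flatnonzero(rest >= 0)
        j1 = j0 + int(nonneg[0]) if nonneg.size else v.size
        t_neg0 = diff.index_to_time(j0)
        t_neg1 = diff.index_to_time(j1)
        if not any(b.start_s < t_neg1 and t_neg0 < b.end_s for b in qualifying_sols):
            continue
        events.append(
            StepEvent(
                side=diff.side,
                peak_time_s=diff.index_to_time(i),
                zero_cross_s=t_neg0,
            )
        )
    return events


def step_cycle_window(
    diff: RelativeDifference,
    event: StepEvent,
    sol_bursts: list[BurstInterval],
) -> StepEvent:
    """Delimit the full step cycle around a detected event.

    Swing starts at the last time at or before the peak where the
    difference is <= 0 (clamped to the segment start, with a warning, if
    the signal is positive from the outset). Stance ends at whichever comes
    first: the difference returning to >= 0 after the flexion-to-extension
    crossing, or the end of the overlapping Sol burst.
    """
    v = diff.values
    i_peak = diff.time_to_index(event.peak_time_s)
    before = np.flatnonzero(v[: i_peak + 1] <= 0)
    if before.size:
        swing_start = diff.index_to_time(int(before[-1]))
    else:
        swing_start = diff.index_to_time(0)
        warnings.warn(
            "difference signal positive from segment start; swing onset "
            "clamped to segment start",
            stacklevel=2,
        )

    j0 = diff.time_to_index(event.zero_cross_s)
    nonneg = np.flatnonzero(v[j0:] >= 0)
    t_return = (
        diff.index_to_time(j0 + int(nonneg[0]))
        if nonneg.size
        else diff.index_to_time(len(v))
    )
    overlapping = [
        b
        for b in sol_bursts
        if b.start_s < t_return and event.zero_cross_s < b.end_s
    ]
    stance_end = t_return
    if overlapping:
        stance_end = min(t_return, max(b.end_s for b in overlapping))
    stance_end = max(stance_end, event.zero_cross_s)
    out = StepEvent(
        side=event.side,
        peak_time_s=event.peak_time_s,
        zero_cross_s=event.zero_cross_s,
        swing_start_s=swing_start,
        stance_end_s=stance_end,
    )
    out.check()
    return out


@dataclass
class ActivityMetrics:
    """Aggregate activity summary over one recording."""

    steps_per_min: np.ndarray  # count per 1-minute bin
    mean_steps_per_min: float
    stance_periods_s: np.ndarray
    mean_stance_s: float
    cumulative_iemg: dict[str, np.ndarray]  # per channel, normalized 0..1
    percent_change_steps: Optional[float] = None


def activity_metrics(
    events: list[StepEvent],
    envelopes: dict[str, Envelope],
    segment_length_s: float,
    reference_step_count: Optional[int] = None,
    iemg_points: int = 100,
) -> ActivityMetrics:
    """Steps/min, stance periods, normalized cumulative IEMG, % change.

    Cumulative IEMG is the running trapezoidal integral of each envelope,
    normalized to [0, 1] over the recording and resampled to
    ``iemg_points`` points. Percent change is detected step count over the
    reference (pre-intervention) count times 100; undefined (None) when the
    reference is zero.
    """
    n_min = max(int(np.ceil(segment_length_s / 60.0)), 1)
    counts = np.zeros(n_min)
    for e in events:
        b = min(int(e.peak_time_s // 60), n_min - 1)
        counts[b] += 1
    stance = np.array(
        [e.stance_period_s for e in events if e.stance_period_s is not None]
    )
    cum: dict[str, np.ndarray] = {}
    for name, env in envelopes.items():
        c = integrate.cumulative_trapezoid(env.values, dx=1.0 / env.rate, initial=0.0)
        total = c[-1]
        c = c / total if total > 0 else c
        idx = np.linspace(0, c.size - 1, iemg_points).round().astype(int)
        cum[name] = c[idx]
    pct: Optional[float] = None
    if reference_step_count is not None:
        if reference_step_count > 0:
            pct = 100.0 * len(events) / reference_step_count
    return ActivityMetrics(
        steps_per_min=counts,
        mean_steps_per_min=float(60.0 * len(events) / segment_length_s),
        stance_periods_s=stance,
        mean_stance_s=float(stance.mean()) if stance.size else float("nan"),
        cumulative_iemg=cum,
        percent_change_steps=pct,
    )


def events_to_frame(events: list[StepEvent]) -> pd.DataFrame:
    """Detected events as a table for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "side": e.side,
                "swing_start_s": e.swing_start_s,
                "peak_time_s": e.peak_time_s,
                "zero_cross_s": e.zero_cross_s,
                "stance_end_s": e.stance_end_s,
            }
            for e in events
        ],
        columns=["side", "swing_start_s", "peak_time_s", "zero_cross_s", "stance_end_s"],
    )
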