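"""Adaptive double thresholding of the EMG envelope.

Long recordings are cut into 10 s bins. Within each bin the quietest
stretch is found by block-averaging the envelope over 10 ms windows,
seeding at the minimum block, and growing the window while the block-mean
first differential stays small and a cumulative log-ramp criterion stays
below its budget (the differential alone misses slow ramping activity).
The rest mean and standard deviation then set the magnitude threshold

    threshold = mu_rest + J * sigma_rest      (J = 7 by default)

and a burst must additionally stay supra-threshold for a channel-specific
minimum duration (flexor TA 0.1 s, extensor Sol 0.3 s) — the "double"
threshold: magnitude AND time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ThresholdingParams
from .conditioning import Envelope
from .io_core import ChannelRole

__all__ = [
    "RestSegment",
    "BurstThreshold",
    "BurstInterval",
    "find_rest_period",
    "compute_threshold",
    "compute_bin_thresholds",
    "detect_bursts",
    "min_duration_for",
    "thresholds_to_frame",
]

MIN_DURATION_S = {"TA": 0.1, "Sol": 0.3}


def min_duration_for(muscle: str, params: Optional[ThresholdingParams] = None) -> float:
    p = params or ThresholdingParams()
    if muscle == "TA":
        return p.min_duration_ta_s
    if muscle == "Sol":
        return p.min_duration_sol_s
    raise ValueError(f"unknown muscle {muscle!r}")


@dataclass
class RestSegment:
    """Quietest contiguous stretch found inside one 10 s bin."""

    bin_index: int
    start_s: float
    end_s: float
    mu_rest: float
    sigma_rest: float
    bin_start_s: float = 0.0
    bin_end_s: float = 0.0

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("rest segment must have end_s > start_s")
        if self.sigma_rest < 0:
            raise ValueError("sigma_rest must be >= 0")


@dataclass
class BurstThreshold:
    """Magnitude + duration criterion for one bin of one channel."""

    bin_index: int
    magnitude: float
    min_duration_s: float
    start_s: float = 0.0
    end_s: float = 0.0
    mu_rest: float = float("nan")
    sigma_rest: float = float("nan")


@dataclass
class BurstInterval:
    """Maximal supra-threshold run meeting the duration criterion.

    Half-open [start_s, end_s) in seconds from recording start.
    """

    start_s: float
    end_s: float
    channel: Optional[ChannelRole] = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


def find_rest_period(
    envelope: Envelope,
    bin_start_s: float,
    bin_end_s: float,
    params: Optional[ThresholdingParams] = None,
    bin_index: int = 0,
) -> RestSegment:
    """Locate the rest stretch inside one bin and compute its statistics.

    Procedure: (1) block-average the envelope over non-overlapping
    ``avg_window_s`` windows; (2) seed at the minimum-mean block (earliest
    on ties); (3) grow the window outward, admitting a neighbouring block
    while the first-differential magnitude of adjacent block means stays
    <= ``dmax`` (in rest-floor fractions per second, the rest floor being
    the seed block mean) and the running log-ramp sum
    sum ln(1 + max(0, m_block - m_seed)/m_seed) stays below ``log_thresh``;
    (4) mu/sigma from the raw envelope samples inside the grown window.

    Both growth criteria are ratios against the seed mean, so the grown
    window — hence mu, sigma, and every threshold built on them — is
    invariant to channel gain. Growth alternates right/left attempts for
    determinism. Setting ``log_thresh`` to None disables the log criterion.
    """
    p = params or ThresholdingParams()
    i0 = envelope.time_to_index(bin_start_s)
    i1 = envelope.time_to_index(bin_end_s)
    i0 = max(i0, 0)
    i1 = min(i1, len(envelope))
    if i1 <= i0:
        raise ValueError("bin lies outside the envelope")
    nb = int(round(p.avg_window_s * envelope.rate))
    if nb < 1:
        raise ValueError("avg_window_s shorter than one sample")
    n_blocks = (i1 - i0) // nb
    if n_blocks < 2:
        raise ValueError(
            f"bin of {(i1 - i0) / envelope.rate:.3f} s holds fewer than 2 "
            f"averaging blocks of {p.avg_window_s} s"
        )
    block_dur = nb / envelope.rate
    blocks = envelope.values[i0 : i0 + n_blocks * nb].reshape(n_blocks, nb)
    means = blocks.mean(axis=1)

    seed = int(np.argmin(means))  # earliest block on exact ties
    mu_seed = means[seed]
    lo = hi = seed
    log_sum = 0.0

    def log_cost(m: float) -> float:
        if p.log_thresh is None:
            return 0.0
        if mu_seed <= 0.0:
            return 0.0 if m <= 0.0 else float("inf")
        return float(np.log1p(max(0.0, m - mu_seed) / mu_seed))

    def admissible(j: int, edge: int) -> Optional[float]:
        step = abs(means[j] - means[edge])
        if mu_seed > 0:
            if step / (block_dur * mu_seed) > p.dmax:
                return None
        elif step > 0:  # zero rest floor: any change is activity
            return None
        c = log_cost(means[j])
        if p.log_thresh is not None and log_sum + c > p.log_thresh:
            return None
        return c

    while True:
        grew = False
        if hi + 1 < n_blocks:
            c = admissible(hi + 1, hi)
            if c is not None:
                hi += 1
                log_sum += c
                grew = True
        if lo - 1 >= 0:
            c = admissible(lo - 1, lo)
            if c is not None:
                lo -= 1
                log_sum += c
                grew = True
        if not grew:
            break

    seg = envelope.values[i0 + lo * nb : i0 + (hi + 1) * nb]
    return RestSegment(
        bin_index=bin_index,
        start_s=envelope.index_to_time(i0 + lo * nb),
        end_s=envelope.index_to_time(i0 + (hi + 1) * nb),
        mu_rest=float(seg.mean()),
        sigma_rest=float(seg.std()),
        bin_start_s=envelope.index_to_time(i0),
        bin_end_s=envelope.index_to_time(i1),
    )


def compute_threshold(
    rest: RestSegment,
    muscle: str = "TA",
    j_scale: float = 7.0,
    params: Optional[ThresholdingParams] = None,
) -> BurstThreshold:
    """Magnitude threshold mu_rest + J*sigma_rest with the channel's
    minimum burst duration."""
    if j_scale <= 0:
        raise ValueError("J must be > 0")
    return BurstThreshold(
        bin_index=rest.bin_index,
        magnitude=rest.mu_rest + j_scale * rest.sigma_rest,
        min_duration_s=min_duration_for(muscle, params),
        start_s=rest.bin_start_s,
        end_s=rest.bin_end_s,
        mu_rest=rest.mu_rest,
        sigma_rest=rest.sigma_rest,
    )


def compute_bin_thresholds(
    envelope: Envelope,
    muscle: str,
    params: Optional[ThresholdingParams] = None,
) -> list[BurstThreshold]:
    """Per-bin thresholds across a whole envelope.

    A trailing partial bin shorter than ``min_partial_bin_s`` inherits the
    previous bin's rest statistics instead of estimating its own from too
    little data.
    """
    p = params or ThresholdingParams()
    duration = envelope.duration_s
    n_full = int(duration // p.bin_s)
    edges = [envelope.t0 + k * p.bin_s for k in range(n_full + 1)]
    remainder = duration - n_full * p.bin_s
    out: list[BurstThreshold] = []
    for k in range(n_full):
        rest = find_rest_period(envelope, edges[k], edges[k + 1], p, bin_index=k)
        out.append(compute_threshold(rest, muscle, p.j_scale, p))
    if remainder > 1e-9:
        start = envelope.t0 + n_full * p.bin_s
        end = envelope.t0 + duration
        if remainder >= p.min_partial_bin_s or not out:
            rest = find_rest_period(envelope, start, end, p, bin_index=n_full)
            out.append(compute_threshold(rest, muscle, p.j_scale, p))
        else:
            prev = out[-1]
            out.append(
                BurstThreshold(
                    bin_index=n_full,
                    magnitude=prev.magnitude,
                    min_duration_s=prev.min_duration_s,
                    start_s=start,
                    end_s=end,
                    mu_rest=prev.mu_rest,
                    sigma_rest=prev.sigma_rest,
                )
            )
    if not out:
        raise ValueError("envelope shorter than one thresholding bin")
    return out


def detect_bursts(
    envelope: Envelope,
    thresholds: list[BurstThreshold],
    channel: Optional[ChannelRole] = None,
) -> list[BurstInterval]:
    """Maximal supra-threshold runs surviving the duration criterion.

    Each sample is compared against its own bin's magnitude threshold, so a
    run crossing a bin boundary is kept as one union run and judged against
    the duration criterion as a whole.
    """
    if not thresholds:
        raise ValueError("no thresholds given")
    thr = np.empty(len(envelope))
    thr.fill(np.nan)
    for t in thresholds:
        a = max(envelope.time_to_index(t.start_s), 0)
        b = min(envelope.time_to_index(t.end_s), len(envelope))
        thr[a:b] = t.magnitude
    if np.isnan(thr).any():
        raise ValueError("thresholds do not cover the envelope span")
    above = envelope.values >= thr
    if not above.any():
        return []
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    ends = list(np.flatnonzero(above[:-1] & ~above[1:]) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(envelope))
    min_dur = thresholds[0].min_duration_s
    out = []
    for s, e in zip(starts, ends):
        if (e - s) / envelope.rate >= min_dur:
            out.append(
                BurstInterval(
                    envelope.index_to_time(s), envelope.index_to_time(e), channel
                )
            )
    return out


def thresholds_to_frame(thresholds: list[BurstThreshold]) -> pd.DataFrame:
    """Per-bin threshold table (for export alongside activity summaries)."""
    return pd.DataFrame(
        [
            {
                "bin_index": t.bin_index,
                "start_s": t.start_s,
                "end_s": t.end_s,
                "mu_rest": t.mu_rest,
                "sigma_rest": t.sigma_rest,
                "threshold": t.magnitude,
            }
            for t in thresholds
        ]
    )
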