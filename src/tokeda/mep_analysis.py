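"""Motor-evoked-potential (MEP) epoching and feature extraction.

Under 40 Hz epidural stimulation each pulse is followed by a 25 ms window
of evoked activity in the band-pass-filtered EMG (never the TKEO
envelope). Epochs are cut at the end of each stimulation pulse and,
when step events are supplied, restricted to epochs lying fully inside a
step cycle (swing onset to stance end). Within each epoch the early,
middle and late responses occupy 1-4, 4-7 and 7-25 ms — conventionally
read as direct/monosynaptic/polysynaptic pathway windows.

Peaks and troughs are detected on a 2x-interpolated trace with a minimum
separation and prominence, then filtered by an absolute second-differential
(curvature) floor so that slow baseline undulations are not counted as
evoked deflections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .config import MepParams
from .io_core import StimPulseLog
from .step_detection import StepEvent

__all__ = [
    "MepWindow",
    "MepFeatures",
    "segment_meps",
    "detect_mep_extrema",
    "mep_features",
    "mep_response_summary",
    "features_to_frame",
]


@dataclass
class MepWindow:
    """One stimulation-locked 25 ms epoch of band-passed EMG (mV)."""

    start_s: float  # pulse end time
    samples: np.ndarray
    rate: float
    peaks: list[tuple[float, float]] = field(default_factory=list)  # (ms, mV)
    troughs: list[tuple[float, float]] = field(default_factory=list)
    in_step_window: bool = True

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class MepFeatures:
    """Scalar features of one MEP epoch."""

    start_s: float
    iemg_mr: float  # mV*ms
    iemg_lr: float  # mV*ms
    peak_to_peak: float  # mV
    n_peaks_er: int
    n_peaks_mr: int
    n_peaks_lr: int
    n_troughs: int = 0


def _epoch_samples(rate: float, epoch_s: float) -> int:
    n = int(round(epoch_s * rate))
    if n < 25:
        raise ValueError(
            f"rate {rate} Hz gives only {n} samples per {epoch_s * 1e3:.0f} ms "
            "epoch; too low for MEP analysis"
        )
    return n


def segment_meps(
    bandpassed: np.ndarray,
    rate: float,
    pulses: StimPulseLog,
    steps: Optional[list[StepEvent]] = None,
    params: Optional[MepParams] = None,
    t0: float = 0.0,
) -> list[MepWindow]:
    """Cut one 25 ms epoch per stimulation pulse end.

    With step events given, only epochs lying fully inside some step
    cycle [swing_start, stance_end] are kept; with ``steps`` None or empty
    all pulses are segmented and the windows are flagged
    ``in_step_window=False``. Epochs running past the recording edge are
    dropped.
    """
    p = params or MepParams()
    x = np.asarray(bandpassed, dtype=float)
    n_ep = _epoch_samples(rate, p.epoch_s)
    use_steps = bool(steps)
    half_sample = 0.5 / rate  # slack against float round-off in pulse times
    windows: list[MepWindow] = []
    for t_end in pulses.pulse_end_times:
        i = int(round((t_end - t0) * rate))
        if i < 0 or i + n_ep > x.size:
            continue  # epoch at recording edge
        if use_steps:
            inside = any(
                s.swing_start_s is not None
                and s.stance_end_s is not None
                and s.swing_start_s - half_sample <= t_end
                and t_end + p.epoch_s <= s.stance_end_s + half_sample
                for s in steps
            )
            if not inside:
                continue
        windows.append(
            MepWindow(
                start_s=float(t_end),
                samples=x[i : i + n_ep],
                rate=rate,
                in_step_window=use_steps,
            )
        )
    return windows


def _interpolate_2x(
    samples: np.ndarray, rate: float, kind: str
) -> tuple[np.ndarray, np.ndarray]:
    """Resample to double the number of points over the same span."""
    n = samples.size
    t = np.arange(n) / rate
    t2 = np.linspace(0.0, t[-1], 2 * n)
    if kind == "linear":
        y2 = np.interp(t2, t, samples)
    else:
        y2 = interpolate.CubicSpline(t, samples)(t2)
    return t2, y2


def detect_mep_extrema(
    mep: MepWindow, params: Optional[MepParams] = None
) -> MepWindow:
    """Fill ``mep.peaks`` and ``mep.troughs`` in place (and return it).

    Pipeline: interpolate to 2x points (piecewise cubic by default); local
    maxima/minima subject to the minimum separation and prominence; keep
    only extrema whose absolute second differential on the interpolated
    grid meets the curvature floor. Times are reported in ms from the
    epoch start. The curvature floor is stored for a nominal sampling rate
    and rescaled by (rate/assumed)^2 when the data rate differs.
    """
    p = params or MepParams()
    t2, y2 = _interpolate_2x(mep.samples, mep.rate, p.interpolation)
    dt = t2[1] - t2[0]
    dist = max(int(np.ceil(p.min_separation_ms * 1e-3 / dt)), 1)

    d2_thresh = p.d2_threshold
    if mep.rate != p.d2_assumed_rate_hz:
        d2_thresh = p.d2_threshold * (mep.rate / p.d2_assumed_rate_hz) ** 2
        warnings.warn(
            f"rescaling curvature floor for rate {mep.rate} Hz "
            f"(assumed {p.d2_assumed_rate_hz} Hz)",
            stacklevel=2,
        )
    # central second difference; endpoints replicate the nearest interior value
    d2 = np.empty_like(y2)
    d2[1:-1] = (y2[2:] - 2 * y2[1:-1] + y2[:-2]) / dt**2
    d2[0], d2[-1] = d2[1], d2[-2]

    def pick(sign: float) -> list[tuple[float, float]]:
        idx, _ = signal.find_peaks(
            sign * y2, distance=dist, prominence=p.min_prominence_mv
        )
        keep = idx[np.abs(d2[idx]) >= d2_thresh]
        return [(float(t2[i] * 1e3), float(y2[i])) for i in keep]

    mep.peaks = pick(+1.0)
    mep.troughs = pick(-1.0)
    return mep


def _window_slice(rate: float, w_ms: tuple[float, float], n: int) -> slice:
    a = int(round(w_ms[0] * 1e-3 * rate))
    b = int(round(w_ms[1] * 1e-3 * rate))
    return slice(max(a, 0), min(b, n))


def mep_features(mep: MepWindow, params: Optional[MepParams] = None) -> MepFeatures:
    """IEMG over the middle/late windows, peak-to-peak, per-window counts.

    IEMG is the rectified area |x|*dt over each half-open sample window
    (mV*ms), so middle + late IEMG equals the IEMG over their 4-25 ms
    union exactly. Peak counts use the detected peak times (troughs are
    tallied separately).
    """
    p = params or MepParams()
    x = mep.samples
    dt_ms = 1e3 / mep.rate
    mr = _window_slice(mep.rate, p.mr_window_ms, x.size)
    lr = _window_slice(mep.rate, p.lr_window_ms, x.size)

    def count(w_ms: tuple[float, float]) -> int:
        return sum(1 for t, _ in mep.peaks if w_ms[0] <= t < w_ms[1])

    return MepFeatures(
        start_s=mep.start_s,
        iemg_mr=float(np.sum(np.abs(x[mr])) * dt_ms),
        iemg_lr=float(np.sum(np.abs(x[lr])) * dt_ms),
        peak_to_peak=float(x.max() - x.min()) if x.size else 0.0,
        n_peaks_er=count(p.er_window_ms),
        n_peaks_mr=count(p.mr_window_ms),
        n_peaks_lr=count(p.lr_window_ms),
        n_troughs=len(mep.troughs),
    )


def mep_response_summary(
    features: list[MepFeatures], reference: list[MepFeatures]
) -> dict[str, Optional[float]]:
    """Total middle/late peak counts as a ratio to a reference condition.

    Ratios are None when the reference total is zero (undefined, reported
    missing rather than silently 0 or inf).
    """
    if not reference:
        raise ValueError("reference feature list must be non-empty")

    def ratio(treat: int, ref: int) -> Optional[float]:
        return treat / ref if ref > 0 else None

    t_mr = sum(f.n_peaks_mr for f in features)
    t_lr = sum(f.n_peaks_lr for f in features)
    r_mr = sum(f.n_peaks_mr for f in reference)
    r_lr = sum(f.n_peaks_lr for f in reference)
    return {"mr_ratio": ratio(t_mr, r_mr), "lr_ratio": ratio(t_lr, r_lr)}


def features_to_frame(
    features: list[MepFeatures], side: str = "", muscle: str = ""
) -> pd.DataFrame:
    """Per-MEP feature table for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "pulse_time_s": f.start_s,
                "side": side,
                "muscle": muscle,
                "n_peaks_er": f.n_peaks_er,
                "n_peaks_mr": f.n_peaks_mr,
                "n_peaks_lr": f.n_peaks_lr,
                "iemg_mr": f.iemg_mr,
                "iemg_lr": f.iemg_lr,
                "peak_to_peak": f.peak_to_peak,
            }
            for f in features
        ],
        columns=[
            "pulse_time_s",
            "side",
            "muscle",
            "n_peaks_er",
            "n_peaks_mr",
            "n_peaks_lr",
            "iemg_mr",
            "iemg_lr",
            "peak_to_peak",
        ],
    )
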