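"""Raw EMG -> activity envelope.

The conditioning chain is: 3rd-order Butterworth band-pass (30-1000 Hz,
zero phase) -> Teager-Kaiser energy operator -> rectification -> zero-phase
50 Hz low-pass. The TKEO, psi[n] = x[n]^2 - x[n-1]*x[n+1], estimates
instantaneous signal energy (amplitude^2 x frequency^2 for a sinusoid) and
sharpens burst onsets relative to plain rectification; the resulting
envelope is therefore on an mV^2 energy scale, not mV.

All filtering is forward-backward (``sosfiltfilt``): the analysis is
offline and downstream step timing depends on undistorted event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .config import ConditioningParams
from .io_core import ChannelRole

__all__ = ["Envelope", "bandpass", "tkeo", "rectify_smooth", "condition"]


@dataclass
class Envelope:
    """Non-negative activity envelope (TKEO energy units, mV^2-scale)."""

    values: np.ndarray
    rate: float
    source_channel: Optional[ChannelRole] = None
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def time_to_index(self, t_s: float) -> int:
        return int(round((t_s - self.t0) * self.rate))

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.rate


def bandpass(
    x: np.ndarray,
    rate: float,
    low: float = 30.0,
    high: float = 1000.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; rejects DC and high-frequency noise.

    ``high`` must stay below the Nyquist frequency.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= rate / 2:
        raise ValueError(f"high cut-off {high} Hz >= Nyquist ({rate / 2} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy: psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Defined for interior samples; the two endpoints replicate the nearest
    interior value so output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("tkeo needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def rectify_smooth(
    x: np.ndarray,
    rate: float,
    cutoff: float = 50.0,
    order: int = 3,
    source_channel: Optional[ChannelRole] = None,
    t0: float = 0.0,
) -> Envelope:
    """Rectify and low-pass into a smooth non-negative envelope.

    Zero-phase Butterworth low-pass on |x|; small negative filter ripple is
    clipped to zero so the envelope honours its non-negativity contract.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({rate / 2} Hz)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, np.abs(x))
    return Envelope(np.clip(smoothed, 0.0, None), rate, source_channel, t0)


def condition(
    x: np.ndarray,
    rate: float,
    params: Optional[ConditioningParams] = None,
    source_channel: Optional[ChannelRole] = None,
    t0: float = 0.0,
) -> Envelope:
    """Full chain: band-pass -> TKEO -> rectify -> smooth.

    Because the TKEO is quadratic, the envelope scales as k^2 when the raw
    signal scales by k; downstream thresholds are built from rest statistics
    of the same envelope, so detection is invariant to channel gain.
    """
    p = params or ConditioningParams()
    bp = bandpass(x, rate, p.band_low_hz, p.band_high_hz, p.band_order)
    return rectify_smooth(
        tkeo(bp), rate, p.smooth_cutoff_hz, p.smooth_order, source_channel, t0
    )
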