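"""Configuration for the TOKEDA pipeline.

Every numeric parameter of the detection chain lives here, grouped by
pipeline stage, with defaults set to the values used for chronic rat
hind-limb recordings (10 kHz intramuscular EMG, 40 Hz sub-threshold
epidural stimulation). A config can be round-tripped through a YAML file
whose top-level sections mirror the dataclasses below.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class ConditioningParams:
    """Band-pass -> TKEO -> rectify/smooth envelope chain.

    band_low_hz/band_high_hz: pass band of the 3rd-order Butterworth
    band-pass applied to raw EMG (rejects DC/motion artifact below 30 Hz
    and high-frequency noise above 1 kHz).
    smooth_cutoff_hz: cut-off of the zero-phase low-pass that smooths the
    rectified TKEO energy into an envelope.
    """

    band_low_hz: float = 30.0
    band_high_hz: float = 1000.0
    band_order: int = 3
    smooth_cutoff_hz: float = 50.0
    smooth_order: int = 3


@dataclass
class ThresholdingParams:
    """Per-bin rest discovery and double (magnitude + duration) threshold.

    The recording is cut into ``bin_s`` bins; within each, block means over
    ``avg_window_s`` locate the quietest window, grown while the block-mean
    first differential stays within ``dmax`` and the cumulative log-ramp
    criterion stays below ``log_thresh`` (set to None to disable). Both
    growth criteria are expressed relative to the bin's rest floor (the
    seed block mean) so that rest discovery — and everything built on it —
    is independent of channel gain: ``dmax`` is in rest-floor fractions per
    second (default 1000/s, i.e. an edge block jumping by more than ten
    rest floors within one 10 ms block step is treated as activity). The
    magnitude threshold is mu_rest + J*sigma_rest; a burst must additionally
    stay supra-threshold for the channel's minimum duration (flexor TA
    0.1 s, extensor Sol 0.3 s).
    """

    bin_s: float = 10.0
    avg_window_s: float = 0.010
    dmax: float = 1000.0
    log_thresh: Optional[float] = 300.0
    j_scale: float = 7.0
    min_duration_ta_s: float = 0.1
    min_duration_sol_s: float = 0.3
    min_partial_bin_s: float = 2.0


@dataclass
class StepDetectionParams:
    """Criteria turning the TA-Sol relative-difference signal into steps.

    follow_window_s: a flexion peak must be followed by a negative
    (extension-dominant) phase within this many seconds.
    diff_threshold: minimum peak magnitude on the normalized difference.
    sol_burst_min_s: minimum duration of the extensor burst overlapping
    the negative phase.
    peak_separation_s: minimum spacing between candidate local maxima.
    """

    follow_window_s: float = 0.5
    diff_threshold: float = 0.01
    sol_burst_min_s: float = 0.25
    peak_separation_s: float = 0.2
    segment_s: float = 600.0  # normalization scope: per 10-minute segment


@dataclass
class MepParams:
    """Stimulation-locked 25 ms epoch segmentation and extrema detection.

    Windows are relative to the end of each stimulation pulse: early
    response [1, 4) ms, middle [4, 7) ms, late [7, 25) ms. Extrema are
    found on a 2x-interpolated trace with a minimum separation, minimum
    prominence, and an absolute second-differential (curvature) floor.
    ``d2_threshold`` is sampling-dependent; it is stored together with the
    rate it assumes and rescaled by (rate/d2_assumed_rate_hz)**2 when the
    data rate differs.
    """

    epoch_s: float = 0.025
    er_window_ms: tuple[float, float] = (1.0, 4.0)
    mr_window_ms: tuple[float, float] = (4.0, 7.0)
    lr_window_ms: tuple[float, float] = (7.0, 25.0)
    min_separation_ms: float = 0.6
    min_prominence_mv: float = 0.2
    d2_threshold: float = 1.5e6
    d2_assumed_rate_hz: float = 10000.0
    interpolation: str = "cubic"  # or "linear"


@dataclass
class StimDetectParams:
    """Stimulation-pulse localisation on the stimulation channel."""

    threshold_mv: Optional[float] = None  # None -> 10x global median |value|
    threshold_median_factor: float = 10.0
    nominal_rate_hz: float = 40.0
    pulse_width_s: float = 0.0002
    rate_tolerance: float = 0.2


@dataclass
class ValidationParams:
    """Event matching against a human annotation log."""

    tolerance_s: float = 0.5


@dataclass
class Config:
    conditioning: ConditioningParams = field(default_factory=ConditioningParams)
    thresholding: ThresholdingParams = field(default_factory=ThresholdingParams)
    step_detection: StepDetectionParams = field(default_factory=StepDetectionParams)
    mep: MepParams = field(default_factory=MepParams)
    stim: StimDetectParams = field(default_factory=StimDetectParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    rate_hz: Optional[float] = None  # fallback when a file carries no rate
    wav_scale_mv: Optional[float] = None  # mV per LSB for integer WAV input

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "conditioning": ConditioningParams,
    "thresholding": ThresholdingParams,
    "step_detection": StepDetectionParams,
    "mep": MepParams,
    "stim": StimDetectParams,
    "validation": ValidationParams,
}


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; missing keys fall back to defaults."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for section, cls in _SECTIONS.items():
        if section in raw and raw[section] is not None:
            current = getattr(cfg, section)
            for key, value in raw[section].items():
                if not hasattr(current, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                setattr(current, key, value)
    for key in ("rate_hz", "wav_scale_mv"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def save_config(cfg: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
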