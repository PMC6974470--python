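"""End-to-end orchestration: recording -> envelopes -> bursts -> steps -> MEPs.

Long recordings are processed in 10-minute segments (the unit over which
channels are normalized); per segment and side, the flexor/extensor pair
is conditioned, thresholded in 10 s bins, and scanned for step-like
events, whose cycle windows then gate MEP epoching.
"""

from __future__ import annotations

from typing import Optional

from .config import Config
from .conditioning import Envelope, bandpass, condition
from .io_core import EmgRecording, StimPulseLog, segment_recording
from .mep_analysis import MepFeatures, detect_mep_extrema, mep_features, segment_meps
from .step_detection import StepEvent, detect_steps, normalize_pair, relative_difference, step_cycle_window
from .thresholding import compute_bin_thresholds, detect_bursts

__all__ = ["detect_steps_recording", "condition_recording", "extract_mep_features"]


def condition_recording(recording: EmgRecording, cfg: Optional[Config] = None) -> dict[str, Envelope]:
    """Activity envelope for every channel, keyed by role name."""
    cfg = cfg or Config()
    out = {}
    for idx, role in recording.channel_roles.items():
        out[role.name] = condition(
            recording.samples[idx],
            recording.rate,
            cfg.conditioning,
            source_channel=role,
            t0=recording.t0,
        )
    return out


def _detect_segment(seg: EmgRecording, side: str, cfg: Config) -> list[StepEvent]:
    ta_env = condition(seg.channel(side, "TA"), seg.rate, cfg.conditioning, t0=seg.t0)
    sol_env = condition(seg.channel(side, "Sol"), seg.rate, cfg.conditioning, t0=seg.t0)
    ta_thr = compute_bin_thresholds(ta_env, "TA", cfg.thresholding)
    sol_thr = compute_bin_thresholds(sol_env, "Sol", cfg.thresholding)
    ta_bursts = detect_bursts(ta_env, ta_thr)
    sol_bursts = detect_bursts(sol_env, sol_thr)
    ta_n, sol_n = normalize_pair(ta_env, sol_env)
    diff = relative_difference(ta_n, sol_n, side, seg.rate, t0=seg.t0)
    events = detect_steps(diff, ta_bursts, sol_bursts, cfg.step_detection)
    return [step_cycle_window(diff, e, sol_bursts) for e in events]


def detect_steps_recording(
    recording: EmgRecording,
    cfg: Optional[Config] = None,
    sides: Optional[list[str]] = None,
) -> list[StepEvent]:
    """Detect step-like events on every side with a full flexor/extensor
    pair, across 10-minute segments; events are in recording time."""
    cfg = cfg or Config()
    sides = sides or recording.sides_with_pair()
    if not sides:
        raise KeyError("no side has both a TA and a Sol channel")
    events: list[StepEvent] = []
    for seg in segment_recording(recording, cfg.step_detection.segment_s):
        for side in sides:
            seg.require_pair(side)
            events.extend(_detect_segment(seg, side, cfg))
    return sorted(events, key=lambda e: e.peak_time_s)


def extract_mep_features(
    recording: EmgRecording,
    pulses: StimPulseLog,
    steps: Optional[list[StepEvent]],
    side: str,
    muscle: str,
    cfg: Optional[Config] = None,
) -> list[MepFeatures]:
    """Band-pass one channel, epoch at pulse ends (optionally restricted to
    step-cycle windows), detect extrema, and compute per-epoch features."""
    cfg = cfg or Config()
    p = cfg.conditioning
    bp = bandpass(
        recording.channel(side, muscle),
        recording.rate,
        p.band_low_hz,
        p.band_high_hz,
        p.band_order,
    )
    side_steps = [e for e in (steps or []) if e.side == side]
    windows = segment_meps(bp, recording.rate, pulses, side_steps, cfg.mep, t0=recording.t0)
    out = []
    for w in windows:
        detect_mep_extrema(w, cfg.mep)
        out.append(mep_features(w, cfg.mep))
    return out
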