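"""Synthetic chronic-EMG generator with known ground truth.

Emulates the structure of overnight home-cage recordings from a spinal
rat: four intramuscular channels (left/right TA and Sol), bout-structured
alternating flexor/extensor bursts on a Gaussian rest baseline, a 40 Hz
sub-threshold stimulation pulse train, and small stimulation-locked evoked
waveforms. Burst texture is amplitude-modulated band-limited Gaussian
noise (30-400 Hz), the standard surrogate for interference-pattern EMG;
no motor-unit-level structure is simulated because only envelope
statistics drive the detection chain.

Bout start times follow an exponentially decaying intensity, mirroring the
post-injection decline of spontaneous activity over a session; each bout
is a run of swing/stance cycles, one ground-truth step event per cycle,
identical on both sides (bilateral stepping) with independent noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .config import MepParams
from .io_core import AnnotationEvent, AnnotationLog, ChannelRole, EmgRecording, StimPulseLog

__all__ = ["MepLobe", "SimConfig", "simulate_recording", "simulate_mep_train", "expected_lobe_detections"]


@dataclass(frozen=True)
class MepLobe:
    """One Gaussian lobe of the evoked-response template.

    amp_mv > 0 is a peak, < 0 a trough; at the lobe centre the curvature is
    |amp| / width^2 (mV/s^2), which determines whether the detector's
    second-differential floor retains it.
    """

    center_ms: float
    width_ms: float
    amp_mv: float

    @property
    def curvature(self) -> float:
        return abs(self.amp_mv) / (self.width_ms * 1e-3) ** 2


DEFAULT_MEP_LOBES: tuple[MepLobe, ...] = (
    MepLobe(2.0, 0.30, 0.50),   # early response
    MepLobe(5.5, 0.35, -0.45),  # middle response
    MepLobe(10.0, 0.40, 0.40),  # late response
    MepLobe(16.0, 0.40, -0.35),
    MepLobe(20.0, 0.40, 0.35),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic recording.

    Defaults describe continuous slow stepping under sub-threshold 40 Hz
    stimulation: ~2 s stance with a short 0.4 s swing, burst amplitude ten
    times the rest noise (SNR 10), and bout onsets decaying exponentially
    over the session.
    """

    rate: float = 10000.0
    duration_s: float = 600.0
    n_step_bouts: int = 10
    steps_per_bout: int = 5
    stance_s: float = 2.0
    swing_s: float = 0.4
    burst_amp_mv: float = 1.0
    rest_noise_mv: float = 0.1
    burst_band_hz: tuple[float, float] = (30.0, 400.0)
    edge_ramp_s: float = 0.05
    inter_bout_gap_s: float = 4.0
    activity_decay_halflife_s: float = 7200.0
    stim_rate_hz: float = 40.0
    stim_pulse_width_s: float = 0.0002
    stim_artifact_mv: float = 0.2
    mep_amp_scale: float = 0.3
    mep_lobes: tuple[MepLobe, ...] = DEFAULT_MEP_LOBES
    include_stim: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("rate", "duration_s", "stance_s", "swing_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rest_noise_mv < 0 or self.burst_amp_mv < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def cycle_s(self) -> float:
        return self.swing_s + self.stance_s


def _band_limited_noise(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    high = min(band[1], 0.45 * rate)
    sos = signal.butter(4, [band[0], high], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _ramped_gate(n: int, starts: np.ndarray, stops: np.ndarray, ramp: int) -> np.ndarray:
    """0/1 gate over [start, stop) index pairs with raised-cosine edges."""
    gate = np.zeros(n)
    for a, b in zip(starts, stops):
        a, b = int(a), int(b)
        gate[a:b] = 1.0
    if ramp > 1:
        win = np.hanning(2 * ramp + 1)
        win /= win.sum()
        gate = np.convolve(gate, win, mode="same")
    return gate


def _mep_template(cfg: SimConfig) -> np.ndarray:
    n = int(round(0.025 * cfg.rate))
    t_ms = np.arange(n) / cfg.rate * 1e3
    out = np.zeros(n)
    for lobe in cfg.mep_lobes:
        out += lobe.amp_mv * np.exp(-0.5 * ((t_ms - lobe.center_ms) / lobe.width_ms) ** 2)
    return out


def _bout_starts(cfg: SimConfig, rng: np.random.Generator) -> list[float]:
    """Bout onsets from a truncated, exponentially decaying intensity."""
    bout_dur = cfg.steps_per_bout * cfg.cycle_s
    horizon = cfg.duration_s - bout_dur
    if horizon <= 0:
        warnings.warn("bout schedule exceeds duration; truncating", stacklevel=3)
        return [0.0] if cfg.n_step_bouts > 0 else []
    tau = cfg.activity_decay_halflife_s / np.log(2.0)
    u = rng.random(cfg.n_step_bouts)
    draws = np.sort(-tau * np.log1p(-u * (1.0 - np.exp(-horizon / tau))))
    starts: list[float] = []
    prev_end = -cfg.inter_bout_gap_s
    truncated = False
    for t in draws:
        t = max(float(t), prev_end + cfg.inter_bout_gap_s)
        if t > horizon:
            truncated = True
            break
        starts.append(t)
        prev_end = t + bout_dur
    if truncated:
        warnings.warn("bout schedule exceeded duration; truncated", stacklevel=3)
    return starts


def simulate_recording(
    cfg: SimConfig,
) -> tuple[EmgRecording, AnnotationLog, StimPulseLog]:
    """Four-channel recording + ground-truth step log + pulse log.

    TA channels burst during swing, Sol channels during stance; rest is
    Gaussian noise of ``rest_noise_mv`` RMS. With ``include_stim``, a
    biphasic pulse artifact and a scaled evoked-response template are added
    at ``stim_rate_hz``. The same seed reproduces the sample path exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    ramp = int(round(cfg.edge_ramp_s * cfg.rate))

    starts = _bout_starts(cfg, rng)
    swing_on, swing_off, stance_on, stance_off = [], [], [], []
    events: list[AnnotationEvent] = []
    for t0 in starts:
        for k in range(cfg.steps_per_bout):
            s = t0 + k * cfg.cycle_s
            swing_on.append(s)
            swing_off.append(s + cfg.swing_s)
            stance_on.append(s + cfg.swing_s)
            stance_off.append(s + cfg.cycle_s)
            for side in ("L", "R"):
                events.append(AnnotationEvent("step", side, s, s + cfg.cycle_s))
    to_idx = lambda ts: np.round(np.asarray(ts) * cfg.rate).astype(int)
    ta_gate = _ramped_gate(n, to_idx(swing_on), to_idx(swing_off), ramp)
    sol_gate = _ramped_gate(n, to_idx(stance_on), to_idx(stance_off), ramp)

    roles = {
        0: ChannelRole("L", "TA"),
        1: ChannelRole("R", "TA"),
        2: ChannelRole("L", "Sol"),
        3: ChannelRole("R", "Sol"),
    }
    samples = np.empty((4, n))
    for idx, role in roles.items():
        gate = ta_gate if role.muscle == "TA" else sol_gate
        burst = _band_limited_noise(rng, n, cfg.rate, cfg.burst_band_hz)
        rest = rng.standard_normal(n) * cfg.rest_noise_mv
        samples[idx] = rest + cfg.burst_amp_mv * gate * burst

    # stimulation pulses and evoked responses
    if cfg.include_stim and cfg.stim_rate_hz > 0:
        width = max(int(round(cfg.stim_pulse_width_s * cfg.rate)), 1)
        period = 1.0 / cfg.stim_rate_hz
        pulse_starts = np.arange(0.0, cfg.duration_s - 0.025, period)
        start_idx = np.round(pulse_starts * cfg.rate).astype(int)
        end_times = (start_idx + width) / cfg.rate
        template = cfg.mep_amp_scale * _mep_template(cfg)
        for idx in range(4):
            ch = samples[idx]
            for i0 in start_idx:
                ch[i0 : i0 + width] += cfg.stim_artifact_mv
                j0 = i0 + width
                j1 = min(j0 + template.size, n)
                ch[j0:j1] += template[: j1 - j0]
        pulses = StimPulseLog(end_times, cfg.stim_rate_hz, cfg.stim_pulse_width_s)
    else:
        pulses = StimPulseLog(np.empty(0), cfg.stim_rate_hz, cfg.stim_pulse_width_s)

    rec = EmgRecording(samples, cfg.rate, roles)
    log = AnnotationLog(events).sorted()
    return rec, log, pulses


def simulate_mep_train(
    cfg: SimConfig,
    n_epochs: int = 10,
    noise_mv: float = 0.0,
    lobes: Optional[Sequence[MepLobe]] = None,
) -> tuple[np.ndarray, list[list[tuple[float, float]]]]:
    """Train of 25 ms epochs with analytically known extrema.

    Each epoch is a sum of well-separated Gaussian lobes, so its extrema
    sit at the lobe centres with the lobe amplitudes. Returns the
    concatenated signal and, per epoch, the (time_ms, amplitude_mv) list of
    true extrema (identical across epochs). Optional additive Gaussian
    noise of ``noise_mv`` RMS.
    """
    rng = np.random.default_rng(cfg.seed)
    use = tuple(lobes) if lobes is not None else cfg.mep_lobes
    base_cfg = SimConfig(rate=cfg.rate, duration_s=cfg.duration_s, mep_lobes=use, seed=cfg.seed)
    template = _mep_template(base_cfg)
    train = np.tile(template, n_epochs)
    if noise_mv > 0:
        train = train + rng.standard_normal(train.size) * noise_mv
    truth = [[(l.center_ms, l.amp_mv) for l in use] for _ in range(n_epochs)]
    return train, truth


def expected_lobe_detections(
    lobes: Sequence[MepLobe], params: Optional[MepParams] = None
) -> tuple[list[MepLobe], list[MepLobe]]:
    """Which lobes the extrema detector should retain, analytically.

    A lobe survives when its amplitude meets the prominence floor and its
    centre curvature |amp|/width^2 meets the second-differential floor.
    Returns (peaks, troughs). Assumes lobe centres are separated by more
    than the minimum-separation rule so no lobe shadows another.
    """
    p = params or MepParams()
    peaks, troughs = [], []
    for l in lobes:
        if abs(l.amp_mv) >= p.min_prominence_mv and l.curvature >= p.d2_threshold:
            (peaks if l.amp_mv > 0 else troughs).append(l)
    return peaks, troughs
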