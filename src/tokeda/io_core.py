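"""Core data containers and file I/O.

Recordings are 2-D arrays (channel x time) in millivolts with a sampling
rate in Hz; channel roles name the side (L/R) and muscle (TA = tibialis
anterior, ankle flexor; Sol = soleus, ankle extensor). Time coordinates
are seconds from recording start, 0-based; intervals are half-open
[onset, offset).

Supported on-disk dialects:
  * delimited text with a header row of channel role names (LTA, RSol, ...)
  * HDF5 with one dataset per channel and a ``rate`` attribute
  * multi-channel WAV (integer or float) with an mV-per-unit scale from config

Annotation and detection logs are delimited text with columns
``label,side,onset_s,offset_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

SIDES = ("L", "R")
MUSCLES = ("TA", "Sol")

__all__ = [
    "ChannelRole",
    "EmgRecording",
    "StimPulseLog",
    "AnnotationEvent",
    "AnnotationLog",
    "read_emg",
    "write_emg",
    "detect_stim_pulses",
    "segment_recording",
    "read_annotations",
    "write_annotations",
    "read_pulse_log",
    "write_pulse_log",
]


@dataclass(frozen=True)
class ChannelRole:
    """Which limb and muscle a channel records."""

    side: str  # "L" or "R"
    muscle: str  # "TA" or "Sol"

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.muscle not in MUSCLES:
            raise ValueError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")

    @property
    def name(self) -> str:
        return f"{self.side}{self.muscle}"

    @classmethod
    def parse(cls, name: str) -> "ChannelRole":
        s = name.strip()
        for side in SIDES:
            for muscle in MUSCLES:
                if s.lower() == f"{side}{muscle}".lower():
                    return cls(side, muscle)
        raise ValueError(
            f"unknown channel role {name!r}; expected one of "
            f"{[s + m for s in SIDES for m in MUSCLES]}"
        )


@dataclass
class EmgRecording:
    """Multi-channel EMG samples in mV with per-channel roles.

    ``samples`` is (n_channels, n_samples); ``channel_roles`` maps channel
    index to its :class:`ChannelRole`. ``t0`` is the recording-start offset
    in seconds (segments of a longer recording keep absolute time).
    """

    samples: np.ndarray
    rate: float
    channel_roles: Mapping[int, ChannelRole]
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channel x time)")
        names = [r.name for r in self.channel_roles.values()]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel roles: {names}")
        for idx in self.channel_roles:
            if not 0 <= idx < self.samples.shape[0]:
                raise ValueError(f"channel index {idx} out of range")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, side: str, muscle: str) -> np.ndarray:
        """1-D samples of the (side, muscle) channel; loud if absent."""
        for idx, role in self.channel_roles.items():
            if role.side == side and role.muscle == muscle:
                return self.samples[idx]
        kind = "flexor" if muscle == "TA" else "extensor"
        raise KeyError(f"missing {kind} channel {side}{muscle}")

    def has_channel(self, side: str, muscle: str) -> bool:
        return any(
            r.side == side and r.muscle == muscle for r in self.channel_roles.values()
        )

    def sides_with_pair(self) -> list[str]:
        """Sides having both the flexor and extensor channel."""
        return [
            s
            for s in SIDES
            if self.has_channel(s, "TA") and self.has_channel(s, "Sol")
        ]

    def require_pair(self, side: str) -> None:
        if not self.has_channel(side, "TA"):
            raise KeyError(f"missing flexor channel {side}TA for step detection")
        if not self.has_channel(side, "Sol"):
            raise KeyError(f"missing extensor channel {side}Sol for step detection")


@dataclass
class StimPulseLog:
    """End times of stimulation pulses, in seconds from recording start."""

    pulse_end_times: np.ndarray
    nominal_rate: float = 40.0
    pulse_width: float = 0.0002

    def __post_init__(self):
        self.pulse_end_times = np.asarray(self.pulse_end_times, dtype=float)
        if self.pulse_end_times.size and np.any(np.diff(self.pulse_end_times) <= 0):
            raise ValueError("pulse_end_times must be strictly increasing")

    def __len__(self) -> int:
        return self.pulse_end_times.size

    def check_rate(self, tolerance: float = 0.2) -> bool:
        """True if inter-pulse gaps match 1/nominal_rate within tolerance."""
        if len(self) < 2:
            return True
        gaps = np.diff(self.pulse_end_times)
        expected = 1.0 / self.nominal_rate
        return bool(np.all(np.abs(gaps - expected) <= tolerance * expected))


@dataclass(frozen=True)
class AnnotationEvent:
    label: str  # "step" or "non_functional"
    side: str
    onset_s: float
    offset_s: float

    def __post_init__(self):
        if not self.onset_s < self.offset_s:
            raise ValueError("onset_s must be < offset_s")


@dataclass
class AnnotationLog:
    events: list[AnnotationEvent] = field(default_factory=list)

    def sorted(self) -> "AnnotationLog":
        return AnnotationLog(sorted(self.events, key=lambda e: e.onset_s))

    def for_side(self, side: str) -> "AnnotationLog":
        return AnnotationLog([e for e in self.events if e.side == side])

    def steps(self) -> list[AnnotationEvent]:
        return [e for e in self.events if e.label == "step"]

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# EMG readers / writers


def _roles_from_names(names: Sequence[str]) -> dict[int, ChannelRole]:
    return {i: ChannelRole.parse(n) for i, n in enumerate(names)}


def read_emg(
    path: str | Path,
    rate: Optional[float] = None,
    channel_names: Optional[Sequence[str]] = None,
    wav_scale_mv: Optional[float] = None,
) -> EmgRecording:
    """Read an EMG recording from delimited text, HDF5, or WAV.

    Delimited text needs a header row of channel role names and an explicit
    ``rate``. HDF5 carries its own rate attribute and per-channel datasets.
    WAV carries the rate; integer samples are scaled by ``wav_scale_mv``
    (mV per least-significant bit), which is then required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if rate is None:
            raise ValueError(f"sampling rate required for delimited file {path}")
        names = channel_names or list(df.columns)
        roles = _roles_from_names(names)
        return EmgRecording(df.to_numpy(dtype=float).T, rate, roles)
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            file_rate = fh.attrs.get("rate")
            if file_rate is None and rate is None:
                raise ValueError(f"HDF5 file {path} has no rate attribute")
            names = list(fh.keys())
            data = np.vstack([fh[name][()] for name in names])
        roles = _roles_from_names(channel_names or names)
        return EmgRecording(data, float(file_rate if file_rate is not None else rate), roles)
    if suffix == ".wav":
        wav_rate, data = wavfile.read(path)
        data = np.atleast_2d(data.T if data.ndim == 2 else data)
        if np.issubdtype(data.dtype, np.integer):
            if wav_scale_mv is None:
                raise ValueError("wav_scale_mv (mV per LSB) required for integer WAV")
            data = data.astype(float) * wav_scale_mv
        else:
            data = data.astype(float) * (wav_scale_mv if wav_scale_mv is not None else 1.0)
        if channel_names is None:
            raise ValueError("channel_names required for WAV input")
        roles = _roles_from_names(channel_names)
        return EmgRecording(data, float(rate if rate is not None else wav_rate), roles)
    raise ValueError(f"unsupported EMG file format: {path.suffix}")


def write_emg(recording: EmgRecording, path: str | Path) -> None:
    """Write a recording as delimited text (.csv/.tsv) or HDF5 (.h5)."""
    path = Path(path)
    suffix = path.suffix.lower()
    names = [
        recording.channel_roles[i].name if i in recording.channel_roles else f"ch{i}"
        for i in range(recording.n_channels)
    ]
    if suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        pd.DataFrame(recording.samples.T, columns=names).to_csv(
            path, sep=sep, index=False
        )
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["rate"] = recording.rate
            fh.attrs["t0"] = recording.t0
            for name, row in zip(names, recording.samples):
                fh.create_dataset(name, data=row)
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


# ---------------------------------------------------------------------------
# Stimulation pulses


def detect_stim_pulses(
    stim_channel: np.ndarray,
    rate: float,
    threshold: Optional[float] = None,
    nominal_rate: float = 40.0,
    pulse_width: float = 0.0002,
    median_factor: float = 10.0,
    t0: float = 0.0,
) -> StimPulseLog:
    """Locate stimulation pulses as supra-threshold runs of |value|.

    A pulse is a maximal run of samples with ``|value| >= threshold``; runs
    separated by fewer than 2 sub-threshold samples are merged. The pulse
    end time is the end of the run's last sample period. With no explicit
    threshold, ``median_factor`` times the channel's global median absolute
    value is used.
    """
    x = np.asarray(stim_channel, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if threshold is None:
        med = float(np.median(np.abs(x)))
        threshold = median_factor * med
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = np.abs(x) >= threshold
    if not above.any():
        warnings.warn("no stimulation pulses found", stacklevel=2)
        return StimPulseLog(np.empty(0), nominal_rate, pulse_width)
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    ends = list(np.flatnonzero(above[:-1] & ~above[1:]))  # inclusive last index
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size - 1)
    # merge runs separated by < 2 samples (a single sub-threshold sample)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] - 1 < 2:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    end_times = t0 + (np.array([e for _, e in merged], dtype=float) + 1.0) / rate
    return StimPulseLog(end_times, nominal_rate, pulse_width)


# ---------------------------------------------------------------------------
# Segmentation of long recordings


def segment_recording(
    recording: EmgRecording, segment_s: float = 600.0
) -> list[EmgRecording]:
    """Split into consecutive segments (default 10 min), keeping the
    trailing partial segment rather than dropping it."""
    if segment_s <= 0:
        raise ValueError("segment_s must be > 0")
    n_seg = int(np.ceil(recording.n_samples / (segment_s * recording.rate)))
    out = []
    step = int(round(segment_s * recording.rate))
    for k in range(max(n_seg, 1)):
        sl = recording.samples[:, k * step : (k + 1) * step]
        if sl.shape[1] == 0:
            break
        out.append(
            EmgRecording(
                sl,
                recording.rate,
                dict(recording.channel_roles),
                t0=recording.t0 + k * step / recording.rate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotation / event logs


def read_annotations(path: str | Path) -> AnnotationLog:
    df = pd.read_csv(path)
    required = {"label", "side", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation log missing columns: {sorted(missing)}")
    events = [
        AnnotationEvent(str(r.label), str(r.side), float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]
    return AnnotationLog(events).sorted()


def write_annotations(log: AnnotationLog, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": e.label,
                "side": e.side,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
            }
            for e in log.events
        ],
        columns=["label", "side", "onset_s", "offset_s"],
    ).to_csv(path, index=False)


def read_pulse_log(path: str | Path) -> StimPulseLog:
    df = pd.read_csv(path)
    return StimPulseLog(df["pulse_end_s"].to_numpy(dtype=float))


def write_pulse_log(log: StimPulseLog, path: str | Path) -> None:
    pd.DataFrame({"pulse_end_s": log.pulse_end_times}).to_csv(path, index=False)
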