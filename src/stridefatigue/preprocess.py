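"""Recording I/O, filtering, magnitude channels, foot-strike detection, stride windows.

A recording is one participant x condition multichannel trunk-IMU time series
(tri-axial accelerometer ``ax, ay, az`` and tri-axial gyroscope
``gx, gy, gz``) sampled at a fixed rate.  Two derived channels are added
per sample:

    amag = sqrt(ax^2 + ay^2 + az^2),   gmag = sqrt(gx^2 + gy^2 + gz^2).

Strides are delimited by foot-strike events detected as prominent peaks in
the (low-pass filtered) vertical acceleration, and each stride is resampled
to a fixed number of points so strides of different durations become
comparable sequences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

#: raw sensor channels in file/column order
RAW_CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

#: fixed 8-channel order of a stride window: accelerometer axes, acceleration
#: magnitude, gyroscope axes, angular-velocity magnitude
CHANNEL_ORDER: tuple[str, ...] = ("ax", "ay", "az", "amag", "gx", "gy", "gz", "gmag")

#: channel key -> feature-name prefix used throughout reporting
CHANNEL_FEATURE_NAMES: dict[str, str] = {
    "ax": "acc_x",
    "ay": "acc_y",
    "az": "acc_z",
    "amag": "acc_mag",
    "gx": "gyro_x",
    "gy": "gyro_y",
    "gz": "gyro_z",
    "gmag": "gyro_mag",
}

#: condition label -> binary code (non-fatigued baseline = 0, fatigued = 1)
CONDITION_CODES: dict[str, int] = {"NF": 0, "F": 1}

VERTICAL_CHANNEL = "az"


class SchemaError(ValueError):
    """A recording file does not match the declared column schema."""


class SegmentationWarning(UserWarning):
    """Raised (as a warning) when a signal cannot be segmented into strides."""


@dataclass
class RawRecording:
    """One participant x condition multichannel IMU time series."""

    participant_id: str
    condition: str
    sampling_rate: float
    t: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_CODES:
            raise ValueError(f"condition must be one of {set(CONDITION_CODES)}")
        n = len(self.t)
        for name, series in self.channels.items():
            if len(series) != n:
                raise ValueError(f"channel {name!r} length {len(series)} != time length {n}")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time vector must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples > 1 else 0.0


@dataclass
class StrideWindow:
    """One time-normalized stride: ``n_points`` samples x 8 channels.

    Channel order is :data:`CHANNEL_ORDER`; ``duration`` is the source
    duration of the stride in seconds before time normalization.
    """

    participant_id: str
    condition: str
    stride_index: int
    data: np.ndarray  # (n_points, 8)
    duration: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNEL_ORDER):
            raise ValueError(f"stride data must be (N, {len(CHANNEL_ORDER)})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stride data must be finite")

    @property
    def n_points(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNEL_ORDER.index(name)]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter specification (order, cutoff, phase mode)."""

    order: int = 4
    cutoff: float = 20.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


# ---------------------------------------------------------------------------
# I/O


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar.

    The CSV holds ``time`` and the six raw channels (derived magnitudes are
    recomputable and not persisted); the sidecar ``<stem>.json`` carries
    participant id, condition, and sampling rate.
    """
    path = Path(path)
    cols = {"time": rec.t}
    cols.update({c: rec.channels[c] for c in RAW_CHANNELS})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")
    meta = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "sampling_rate": rec.sampling_rate,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`SchemaError` naming the first missing column; a
    non-monotone time axis is rejected by :class:`RawRecording` validation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time",) + RAW_CHANNELS:
        if col not in df.columns:
            raise SchemaError(f"recording {path.name} is missing column {col!r}")
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise SchemaError(f"missing metadata sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    return RawRecording(
        participant_id=str(meta["participant_id"]),
        condition=str(meta["condition"]),
        sampling_rate=float(meta["sampling_rate"]),
        t=df["time"].to_numpy(float),
        channels={c: df[c].to_numpy(float) for c in RAW_CHANNELS},
    )


# ---------------------------------------------------------------------------
# Filtering and derived channels


def lowpass_filter(series: np.ndarray, sampling_rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass Butterworth filter of one series, zero-phase by default.

    Zero-phase (forward-backward) application preserves event timing; the
    effective magnitude response is the squared single-pass response.
    """
    series = np.asarray(series, dtype=float)
    nyquist = sampling_rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz")
    if len(series) <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=sampling_rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, series)
    return signal.sosfilt(sos, series)


def filter_recording(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Apply the low-pass filter to the six raw channels of a recording.

    Magnitude channels, if present, are dropped: they are derived from the
    filtered axes afterwards (see :func:`add_magnitude_channels`).
    """
    filtered = {c: lowpass_filter(rec.channels[c], rec.sampling_rate, spec) for c in RAW_CHANNELS}
    return replace(rec, channels=filtered)


def add_magnitude_channels(rec: RawRecording) -> RawRecording:
    """Append Euclidean magnitude channels amag and gmag."""
    ch = dict(rec.channels)
    ch["amag"] = np.sqrt(ch["ax"] ** 2 + ch["ay"] ** 2 + ch["az"] ** 2)
    ch["gmag"] = np.sqrt(ch["gx"] ** 2 + ch["gy"] ** 2 + ch["gz"] ** 2)
    return replace(rec, channels=ch)


# ---------------------------------------------------------------------------
# Segmentation


def detect_foot_strikes(
    vertical: np.ndarray,
    sampling_rate: float,
    max_stride_frequency: float = 2.0,
    prominence_factor: float = 0.5,
) -> np.ndarray:
    """Detect foot-strike events as prominent peaks in vertical acceleration.

    The minimum peak separation is half the shortest plausible stride period
    (``0.5 / max_stride_frequency`` seconds) and the prominence threshold is
    ``prominence_factor`` times the standard deviation of the series, so the
    detector adapts to the signal's amplitude scale.  Fewer than two events
    means no complete stride exists; a :class:`SegmentationWarning` is issued
    and whatever was found is returned.
    """
    vertical = np.asarray(vertical, dtype=float)
    sd = float(np.std(vertical))
    if sd == 0.0:
        warnings.warn("constant signal: no foot strikes detectable", SegmentationWarning)
        return np.array([], dtype=int)
    distance = max(1, int(round(0.5 / max_stride_frequency * sampling_rate)))
    peaks, _ = signal.find_peaks(vertical, distance=distance, prominence=prominence_factor * sd)
    if len(peaks) < 2:
        warnings.warn(
            f"only {len(peaks)} foot-strike event(s) detected: signal cannot be segmented",
            SegmentationWarning,
        )
    return peaks.astype(int)


def segment_and_normalize(
    rec: RawRecording,
    events: np.ndarray,
    n_points: int = 128,
) -> list[StrideWindow]:
    """Cut half-open stride windows between consecutive events and resample.

    Each window ``[e_k, e_{k+1})`` is linearly interpolated onto ``n_points``
    equispaced phase points (phase 0 maps to the event sample, phase
    ``(n_points-1)/n_points`` to just before the next event), making strides
    disjoint and exhaustive between the first and last event.  Windows
    shorter than 4 samples are dropped with a warning.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise ValueError("need at least 2 events to cut a stride window")
    rec_full = rec if "amag" in rec.channels else add_magnitude_channels(rec)
    series = np.column_stack([rec_full.channels[c] for c in CHANNEL_ORDER])
    sample_idx = np.arange(series.shape[0], dtype=float)

    windows: list[StrideWindow] = []
    stride_index = 0
    for e0, e1 in zip(events[:-1], events[1:]):
        length = e1 - e0
        if length < 4:
            warnings.warn(
                f"stride window at sample {e0} has only {length} samples; dropped",
                SegmentationWarning,
            )
            continue
        grid = e0 + np.arange(n_points) / n_points * length
        data = np.column_stack(
            [np.interp(grid, sample_idx, series[:, j]) for j in range(series.shape[1])]
        )
        windows.append(
            StrideWindow(
                participant_id=rec.participant_id,
                condition=rec.condition,
                stride_index=stride_index,
                data=data,
                duration=length / rec.sampling_rate,
            )
        )
        stride_index += 1
    return windows


def segment_recording(
    rec: RawRecording,
    spec: FilterSpec = FilterSpec(),
    n_points: int = 128,
    max_stride_frequency: float = 2.0,
    prominence_factor: float = 0.5,
) -> list[StrideWindow]:
    """Filter, derive magnitudes, detect foot strikes, and cut stride windows."""
    filtered = add_magnitude_channels(filter_recording(rec, spec))
    events = detect_foot_strikes(
        filtered.channels[VERTICAL_CHANNEL],
        rec.sampling_rate,
        max_stride_frequency=max_stride_frequency,
        prominence_factor=prominence_factor,
    )
    if len(events) < 2:
        return []
    return segment_and_normalize(filtered, events, n_points=n_points)


# ---------------------------------------------------------------------------
# Stride-window persistence (long table: one row per sample)


def windows_to_frame(windows: list[StrideWindow]) -> pd.DataFrame:
    """Persistable long table: participant, condition, stride_index, sample_index, channels, duration."""
    frames = []
    for w in windows:
        df = pd.DataFrame(w.data, columns=list(CHANNEL_ORDER))
        df.insert(0, "sample_index", np.arange(w.n_points))
        df.insert(0, "stride_index", w.stride_index)
        df.insert(0, "condition", w.condition)
        df.insert(0, "participant", w.participant_id)
        df["duration"] = w.duration
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["participant", "condition", "stride_index", "sample_index"]
            + list(CHANNEL_ORDER)
            + ["duration"]
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_windows(df: pd.DataFrame) -> list[StrideWindow]:
    """Inverse of :func:`windows_to_frame`."""
    required = {"participant", "condition", "stride_index", "sample_index", "duration"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"stride table is missing column(s) {sorted(missing)}")
    windows = []
    for (pid, cond, idx), grp in df.groupby(["participant", "condition", "stride_index"], sort=True):
        grp = grp.sort_values("sample_index")
        windows.append(
            StrideWindow(
                participant_id=str(pid),
                condition=str(cond),
                stride_index=int(idx),
                data=grp[list(CHANNEL_ORDER)].to_numpy(float),
                duration=float(grp["duration"].iloc[0]),
            )
        )
    return windows
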