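"""Seeded synthetic IMU running cohorts with known fatigue ground truth.

The generator emulates a lumbar-mounted IMU during 400 m runs: roughly 19
runners, two labeled run segments each (non-fatigued NF and fatigued F),
50-80 strides per segment at 256 Hz.  Each channel is a small harmonic sum
of the stride frequency; the vertical accelerometer additionally carries one
Gaussian impact pulse per stride at foot strike.  Fatigue is injected with
the effect directions observed in the study this pipeline reimplements:
vertical mean down, lateral peaks up, sharper impacts (kurtosis up), more
rotational activity (gyro RMS up), and more irregularity (amplitude noise
and stride-timing jitter both inflated).  Per-participant random intercepts
shift every channel's DC level, creating the between-runner heterogeneity
that separates population-level from personalized modeling.

Units are arbitrary "m/s^2-like" and "deg/s-like" scales; the generator aims
at effect directions and hierarchical structure, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .preprocess import RAW_CHANNELS, RawRecording

VERTICAL = "az"
LATERAL = "ay"
GYRO_CHANNELS = ("gx", "gy", "gz")


@dataclass(frozen=True)
class ChannelWave:
    """Harmonic description of one channel: DC offset plus sinusoid amplitudes/phases."""

    dc: float
    amps: tuple[float, ...]
    phases: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amps) != len(self.phases):
            raise ValueError("amps and phases must have equal length")
        vals = (self.dc, *self.amps, *self.phases)
        if not np.all(np.isfinite(vals)):
            raise ValueError("waveform parameters must be finite")


def default_waves() -> dict[str, ChannelWave]:
    # Accelerometer in m/s^2-like units (vertical rides on gravity),
    # gyroscope in deg/s-like units; 3 harmonics of the stride frequency.
    return {
        "ax": ChannelWave(0.3, (1.0, 0.5, 0.2), (0.0, 0.7, 1.3)),
        "ay": ChannelWave(0.5, (1.2, 0.4, 0.2), (0.4, 1.1, 2.0)),
        "az": ChannelWave(9.8, (0.8, 0.4, 0.2), (0.2, 0.9, 1.7)),
        "gx": ChannelWave(0.0, (30.0, 10.0, 5.0), (0.1, 0.8, 1.5)),
        "gy": ChannelWave(0.0, (40.0, 15.0, 5.0), (0.5, 1.2, 1.9)),
        "gz": ChannelWave(0.0, (25.0, 10.0, 5.0), (0.3, 1.0, 1.8)),
    }


@dataclass(frozen=True)
class FatigueEffects:
    """Signed fatigue deltas applied to F-condition recordings.

    delta_vertical_mean shifts the vertical DC (propulsion down);
    delta_lateral_peak adds to the fundamental lateral amplitude (peaks up);
    impact_sharpen_factor divides the impact-pulse width (kurtosis up);
    rotational_gain multiplies gyro harmonic amplitudes (rotational RMS up);
    noise_inflation / jitter_inflation multiply the amplitude-noise SD and
    the stride-period jitter SD (irregularity and entropy up).
    """

    delta_vertical_mean: float = -0.8
    delta_lateral_peak: float = 1.5
    impact_sharpen_factor: float = 1.5
    rotational_gain: float = 1.15
    noise_inflation: float = 1.5
    jitter_inflation: float = 1.5

    def __post_init__(self) -> None:
        if self.impact_sharpen_factor <= 0:
            raise ValueError("impact_sharpen_factor must be > 0")
        if self.noise_inflation < 1 or self.jitter_inflation < 1:
            raise ValueError("inflation factors must be >= 1")
        if self.rotational_gain <= 0:
            raise ValueError("rotational_gain must be > 0")


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level configuration; fixed seed + fixed config gives bit-identical output."""

    n_participants: int = 19
    strides_per_condition: tuple[int, int] = (50, 80)  # inclusive range per 400 m run
    sampling_rate: float = 256.0
    stride_frequency_mean: float = 1.3
    stride_frequency_sd: float = 0.08
    waves: Mapping[str, ChannelWave] = field(default_factory=default_waves)
    impact_amplitude: float = 8.0
    impact_width: float = 0.05  # seconds (Gaussian sigma of the impact pulse)
    noise_sd: float = 0.3
    timing_jitter_sd: float = 0.02  # fraction of the stride period
    # slow stride-to-stride modulation of the oscillatory signal content
    # (a pacing-fluctuation surrogate): AC gain = 1 + drift * sin(2 pi k / period)
    amplitude_drift: float = 0.3
    drift_period_strides: float = 20.0
    # white per-stride amplitude variability (stride-to-stride force variation);
    # inflated under F by the noise_inflation factor, and further raised by the
    # smooth-drift variance that fatigue converts into noise
    stride_gain_noise_sd: float = 0.08
    fatigue: FatigueEffects = field(default_factory=FatigueEffects)
    random_intercept_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.strides_per_condition
        if self.n_participants < 1 or lo < 1 or hi < lo:
            raise ValueError("counts must be >= 1 and the stride range non-empty")
        n_harm = max(len(w.amps) for w in self.waves.values())
        f_max = n_harm * (self.stride_frequency_mean + 4 * self.stride_frequency_sd)
        if self.sampling_rate <= 2 * f_max:
            raise ValueError("sampling_rate must exceed twice the highest harmonic frequency")
        if self.noise_sd < 0 or self.timing_jitter_sd < 0 or self.random_intercept_sd < 0:
            raise ValueError("noise, jitter and intercept SDs must be >= 0")
        if self.impact_width <= 0 or self.impact_amplitude < 0:
            raise ValueError("impact pulse must have positive width and non-negative amplitude")
        if self.amplitude_drift < 0 or self.drift_period_strides <= 0:
            raise ValueError("amplitude drift must be >= 0 with a positive period")
        if self.stride_gain_noise_sd < 0:
            raise ValueError("stride gain noise SD must be >= 0")
        if set(self.waves) != set(RAW_CHANNELS):
            raise ValueError(f"waves must define exactly the channels {RAW_CHANNELS}")


@dataclass(frozen=True)
class WaveformParams:
    """Fully resolved per-stride waveform parameters for the six raw channels."""

    waves: Mapping[str, ChannelWave]
    impact_amplitude: float
    impact_width_phase: float  # Gaussian sigma in stride-phase units

    def __post_init__(self) -> None:
        if not np.isfinite(self.impact_amplitude) or not np.isfinite(self.impact_width_phase):
            raise ValueError("impact parameters must be finite")
        if self.impact_width_phase <= 0:
            raise ValueError("impact width must be positive")


@dataclass
class GroundTruth:
    """Oracle bookkeeping: intercepts, stride frequencies, true event times per recording."""

    intercepts: dict[str, float] = field(default_factory=dict)
    stride_frequency: dict[str, float] = field(default_factory=dict)
    events: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_strides: dict[tuple[str, str], int] = field(default_factory=dict)

    def check(self) -> None:
        for key, ev in self.events.items():
            if not np.all(np.diff(ev) > 0):
                raise ValueError(f"ground-truth event times not strictly increasing for {key}")


def generate_stride_waveform(phase_grid: np.ndarray, params: WaveformParams) -> np.ndarray:
    """Evaluate the six raw channels on a sorted phase grid in [0, 1).

    Each channel is ``dc + sum_h A_h sin(2 pi (h+1) phi + theta_h)``; the
    vertical channel adds one Gaussian impact pulse centered at phase 0
    (circular, so the pulse also ramps up just before the next foot strike).
    Returns an ``(len(phase_grid), 6)`` block in :data:`RAW_CHANNELS` order.
    """
    phi = np.asarray(phase_grid, dtype=float)
    if phi.ndim != 1:
        raise ValueError("phase_grid must be 1-D")
    if len(phi) and (phi.min() < 0 or phi.max() >= 1):
        raise ValueError("phase_grid values must lie in [0, 1)")
    if len(phi) > 1 and np.any(np.diff(phi) < 0):
        raise ValueError("phase_grid must be sorted")

    out = np.empty((len(phi), len(RAW_CHANNELS)))
    for j, name in enumerate(RAW_CHANNELS):
        w = params.waves[name]
        y = np.full(len(phi), w.dc)
        for h, (a, th) in enumerate(zip(w.amps, w.phases), start=1):
            y += a * np.sin(2 * np.pi * h * phi + th)
        if name == VERTICAL and params.impact_amplitude > 0:
            d = np.minimum(phi, 1.0 - phi)  # circular distance to foot strike
            y += params.impact_amplitude * np.exp(-0.5 * (d / params.impact_width_phase) ** 2)
        out[:, j] = y
    return out


def _condition_params(
    cfg: SynthConfig, condition: str, intercept: float, stride_frequency: float
) -> tuple[WaveformParams, float, float]:
    """Resolve waveform parameters, noise SD, and jitter SD for one recording."""
    fat = cfg.fatigue
    fatigued = condition == "F"
    waves: dict[str, ChannelWave] = {}
    for name, w in cfg.waves.items():
        dc = w.dc + intercept
        amps = list(w.amps)
        if fatigued:
            if name == VERTICAL:
                dc += fat.delta_vertical_mean
            if name == LATERAL and amps:
                amps[0] += fat.delta_lateral_peak
            if name in GYRO_CHANNELS:
                amps = [a * fat.rotational_gain for a in amps]
        waves[name] = ChannelWave(dc, tuple(amps), w.phases)
    # Sharpening is area-preserving (amplitude x factor, width / factor) so the
    # impact pulse raises kurtosis without moving the vertical channel mean:
    # the configured delta_vertical_mean stays the whole mean effect.
    sharpen = fat.impact_sharpen_factor if fatigued else 1.0
    width_phase = (cfg.impact_width / sharpen) * stride_frequency
    params = WaveformParams(waves, cfg.impact_amplitude * sharpen, width_phase)
    noise_sd = cfg.noise_sd * (fat.noise_inflation if fatigued else 1.0)
    jitter_sd = cfg.timing_jitter_sd * (fat.jitter_inflation if fatigued else 1.0)
    return params, noise_sd, jitter_sd


def generate_recording(
    cfg: SynthConfig,
    participant_id: str,
    condition: str,
    n_strides: int,
    rng: np.random.Generator,
    intercept: float = 0.0,
    stride_frequency: float | None = None,
) -> tuple[RawRecording, np.ndarray]:
    """Generate one labeled run segment and its true foot-strike times.

    Strides are concatenated with per-stride periods jittered around the
    participant's nominal period; white amplitude noise is added to every
    channel.  Under the F condition the configured fatigue deltas apply.
    Returns the recording and the ``n_strides + 1`` true event times
    (stride boundaries) in seconds.
    """
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")
    f_p = cfg.stride_frequency_mean if stride_frequency is None else stride_frequency
    params, noise_sd, jitter_sd = _condition_params(cfg, condition, intercept, f_p)

    period = 1.0 / f_p
    factors = np.clip(1.0 + jitter_sd * rng.standard_normal(n_strides), 0.5, 1.5)
    periods = period * factors
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])  # n_strides + 1 event times

    fs = cfg.sampling_rate
    n_samples = int(np.floor(boundaries[-1] * fs))
    t = np.arange(n_samples) / fs
    stride_of = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, n_strides - 1)

    # stride-to-stride gain on the oscillatory content: a smooth pacing drift
    # plus white per-stride force variability (the latter inflated under F)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    fatigued = condition == "F"
    drift_amp = cfg.amplitude_drift
    gain_noise_sd = cfg.stride_gain_noise_sd
    if fatigued:
        # fatigue erodes the smooth pacing structure: the autocorrelated drift
        # is attenuated by jitter_inflation and the variance it loses is
        # converted into white stride-to-stride variability, on top of the
        # noise_inflation applied to the white component itself.  Structure
        # becomes noise; total gain variability never decreases.
        att = cfg.fatigue.jitter_inflation
        drift_amp = cfg.amplitude_drift / att
        lost_var = cfg.amplitude_drift**2 / 2.0 * (1.0 - 1.0 / att**2)
        gain_noise_sd = np.sqrt(
            (cfg.stride_gain_noise_sd * cfg.fatigue.noise_inflation) ** 2 + lost_var
        )
    gains = (
        1.0
        + drift_amp
        * np.sin(2.0 * np.pi * np.arange(n_strides) / cfg.drift_period_strides + drift_phase)
        + gain_noise_sd * rng.standard_normal(n_strides)
    )
    dc_row = np.array([params.waves[name].dc for name in RAW_CHANNELS])

    data = np.empty((n_samples, len(RAW_CHANNELS)))
    for k in range(n_strides):
        mask = stride_of == k
        phi = (t[mask] - boundaries[k]) / periods[k]
        wave = generate_stride_waveform(np.clip(phi, 0.0, np.nextafter(1.0, 0.0)), params)
        data[mask] = dc_row + gains[k] * (wave - dc_row)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    rec = RawRecording(
        participant_id=participant_id,
        condition=condition,
        sampling_rate=fs,
        t=t,
        channels={name: data[:, j].copy() for j, name in enumerate(RAW_CHANNELS)},
    )
    return rec, boundaries


def generate_cohort(cfg: SynthConfig) -> tuple[list[RawRecording], GroundTruth]:
    """Generate the full cohort: one NF and one F recording per participant.

    Each participant draws a random intercept (added to every channel's DC
    level), a nominal stride frequency, and a stride count per condition
    from the configured range.  All randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.strides_per_condition
    recordings: list[RawRecording] = []
    truth = GroundTruth()
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:02d}"
        intercept = float(rng.normal(0.0, cfg.random_intercept_sd))
        f_p = float(
            np.clip(
                rng.normal(cfg.stride_frequency_mean, cfg.stride_frequency_sd),
                0.5 * cfg.stride_frequency_mean,
                1.5 * cfg.stride_frequency_mean,
            )
        )
        truth.intercepts[pid] = intercept
        truth.stride_frequency[pid] = f_p
        for condition in ("NF", "F"):
            n_strides = int(rng.integers(lo, hi + 1))
            rec, events = generate_recording(
                cfg, pid, condition, n_strides, rng, intercept=intercept, stride_frequency=f_p
            )
            recordings.append(rec)
            truth.events[(pid, condition)] = events
            truth.n_strides[(pid, condition)] = n_strides
    truth.check()
    return recordings, truth
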