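"""Per-stride time-domain, spectral, and entropy features.

Each time-normalized stride yields, per channel, the eight moment/energy
statistics (mean, std, rms, min, max, skew, kurt, energy) forming the
64-column base feature matrix, plus spectral extensions (dominant frequency,
spectral entropy, bandpowers) and sample entropy.  Moments use population
(1/N) definitions and kurtosis is non-excess (a Gaussian tends to 3).

Sample entropy follows the standard template-matching formulation: with
tolerance ``r`` expressed as a fraction of the series standard deviation,
``B`` counts ordered template pairs of length ``m`` within Chebyshev
distance ``r * sd`` and ``A`` the same for length ``m + 1`` (both restricted
to templates that admit an (m+1)-point extension); SampEn = -ln(A/B).
Higher values mean a more irregular, less predictable series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CHANNEL_FEATURE_NAMES, CHANNEL_ORDER, CONDITION_CODES, StrideWindow

#: the eight base statistics per channel (8 channels x 8 stats = 64 columns)
BASE_STATS: tuple[str, ...] = ("mean", "std", "rms", "min", "max", "skew", "kurt", "energy")

KEY_COLUMNS: tuple[str, ...] = ("participant", "condition", "stride_index")


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r: float = 0.2  # tolerance as a fraction of the series SD

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be > 0")


@dataclass(frozen=True)
class BandSpec:
    """Ordered, non-overlapping half-open frequency bands [f1, f2) in Hz."""

    bands: tuple[tuple[float, float], ...] = ((0.5, 3.0), (3.0, 8.0), (8.0, 20.0))

    def __post_init__(self) -> None:
        prev = 0.0
        for f1, f2 in self.bands:
            if not (0.0 <= f1 < f2):
                raise ValueError(f"band [{f1}, {f2}) is not increasing")
            if f1 < prev:
                raise ValueError("bands must be non-overlapping and increasing")
            prev = f2


def time_domain_features(series: np.ndarray) -> dict[str, float]:
    """Population moments, extremes and energy of one series.

    A zero-variance series returns skew = kurt = 0 together with
    ``degenerate=True`` (a policy flag, not a feature column) so one flat
    stride cannot abort a cohort run.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    mean = float(np.mean(x))
    var = float(np.mean((x - mean) ** 2))
    std = float(np.sqrt(var))
    degenerate = var == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    return {
        "mean": mean,
        "std": std,
        "rms": float(np.sqrt(np.mean(x**2))),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "skew": skew,
        "kurt": kurt,
        "energy": float(np.sum(x**2)),
        "degenerate": degenerate,
    }


def spectral_features(
    series: np.ndarray,
    effective_rate: float,
    bands: BandSpec = BandSpec(),
) -> dict[str, float]:
    """Dominant frequency, spectral entropy (nats) and bandpowers of one stride.

    The one-sided FFT power spectrum excludes the DC bin so the stride mean
    does not masquerade as periodicity.  For a time-normalized stride the
    frequency axis uses the stride's effective rate ``n_points / duration``,
    which preserves physical Hz.  An all-zero AC spectrum yields
    ``fdom = nan`` and ``specent = 0`` by convention.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series too short for spectral features")
    if effective_rate <= 0:
        raise ValueError("effective_rate must be positive")
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum[1:]) ** 2  # DC excluded
    freqs = np.fft.rfftfreq(n, d=1.0 / effective_rate)[1:]

    out: dict[str, float] = {}
    total = float(power.sum())
    if total <= 0.0:
        out["fdom"] = float("nan")
        out["specent"] = 0.0
    else:
        out["fdom"] = float(freqs[int(np.argmax(power))])
        p = power / total
        nz = p[p > 0]
        out["specent"] = float(-np.sum(nz * np.log(nz)))
    for i, (f1, f2) in enumerate(bands.bands, start=1):
        sel = (freqs >= f1) & (freqs < f2)
        out[f"bp{i}"] = float(power[sel].sum())
    return out


def sample_entropy(series: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy -ln(A/B); ``nan`` when no template pair matches.

    ``nan`` is the explicit "incomputable" sentinel: a zero match count is
    never silently turned into +/- infinity.
    """
    x = np.asarray(series, dtype=float)
    m = params.m
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series length {n} < m + 2 = {m + 2}")
    sd = float(np.std(x))
    tol = params.r * sd
    n_templates = n - m  # templates of length m that admit an (m+1)-extension

    # pairwise Chebyshev distances built up one template offset at a time
    d_m = np.zeros((n_templates, n_templates))
    for k in range(m):
        seg = x[k : k + n_templates]
        d_m = np.maximum(d_m, np.abs(seg[:, None] - seg[None, :]))
    off_diag = ~np.eye(n_templates, dtype=bool)
    b_count = int(np.sum((d_m <= tol) & off_diag))

    seg = x[m : m + n_templates]
    d_m1 = np.maximum(d_m, np.abs(seg[:, None] - seg[None, :]))
    a_count = int(np.sum((d_m1 <= tol) & off_diag))

    if a_count == 0 or b_count == 0:
        return float("nan")
    return float(-np.log(a_count / b_count))


def build_feature_table(
    windows: list[StrideWindow],
    sampen: SampEnParams = SampEnParams(),
    bands: BandSpec = BandSpec(),
    include_extended: bool = True,
) -> pd.DataFrame:
    """Assemble the labeled per-stride feature table.

    One row per stride, keyed by (participant, condition, stride_index) with
    the condition coded 0 (NF) / 1 (F).  Base columns are named
    ``{acc|gyro}_{x|y|z|mag}_{stat}``; extended columns carry the suffixes
    ``_fdom``, ``_specent``, ``_bp{i}`` and ``_sampen``.  An incomputable
    sample entropy propagates as a missing value in its extended column only.
    """
    if not windows:
        raise ValueError("no stride windows provided")
    n_points = windows[0].n_points
    rows = []
    for w in windows:
        if w.n_points != n_points:
            raise ValueError("all stride windows must share the same n_points")
        row: dict[str, float] = {
            "participant": w.participant_id,
            "condition": CONDITION_CODES[w.condition],
            "stride_index": w.stride_index,
        }
        eff_rate = w.n_points / w.duration
        for j, ch in enumerate(CHANNEL_ORDER):
            name = CHANNEL_FEATURE_NAMES[ch]
            series = w.data[:, j]
            td = time_domain_features(series)
            for stat in BASE_STATS:
                row[f"{name}_{stat}"] = td[stat]
            if include_extended:
                for key, val in spectral_features(series, eff_rate, bands).items():
                    row[f"{name}_{key}"] = val
                row[f"{name}_sampen"] = sample_entropy(series, sampen)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.duplicated(subset=list(KEY_COLUMNS)).any():
        raise ValueError("duplicate (participant, condition, stride_index) keys")
    return table


def base_feature_columns() -> list[str]:
    """The 64 base feature column names in channel-major order."""
    return [
        f"{CHANNEL_FEATURE_NAMES[ch]}_{stat}" for ch in CHANNEL_ORDER for stat in BASE_STATS
    ]


def feature_columns(table: pd.DataFrame, feature_set: str = "base") -> list[str]:
    """Select model input columns: the base 64 or base plus extended."""
    base = base_feature_columns()
    if feature_set == "base":
        return base
    if feature_set == "extended":
        extra = [
            c for c in table.columns if c not in base and c not in KEY_COLUMNS
        ]
        return base + extra
    raise ValueError(f"unknown feature_set {feature_set!r}")
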