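"""Shared fixtures: synthetic cohorts, feature tables, and simulation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stridefatigue import SynthConfig, build_feature_table, generate_cohort
from stridefatigue.features import base_feature_columns
from stridefatigue.preprocess import segment_recording


def make_feature_table(
    cfg: SynthConfig, include_extended: bool = False
) -> pd.DataFrame:
    """Full path: simulate -> filter -> segment -> features."""
    recordings, _ = generate_cohort(cfg)
    windows = []
    for rec in recordings:
        windows.extend(segment_recording(rec))
    return build_feature_table(windows, include_extended=include_extended)


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    """Default-effect cohort of 4 runners, base features only (fast, reused)."""
    cfg = SynthConfig(n_participants=4, strides_per_condition=(18, 22), seed=7)
    return make_feature_table(cfg)


def simulate_lmm_data(
    n_participants: int,
    strides_per_participant: int,
    beta0: float,
    beta1: float,
    sigma_u: float,
    sigma_e: float,
    seed: int,
) -> pd.DataFrame:
    """Direct random-intercept data: y = b0 + b1*cond + u_j + eps (balanced)."""
    rng = np.random.default_rng(seed)
    half = strides_per_participant // 2
    groups = np.repeat([f"P{j:02d}" for j in range(n_participants)], 2 * half)
    cond = np.tile(np.r_[np.zeros(half), np.ones(half)], n_participants)
    u = rng.normal(0.0, sigma_u, n_participants)
    y = beta0 + beta1 * cond + np.repeat(u, 2 * half) + rng.normal(0.0, sigma_e, len(cond))
    return pd.DataFrame(
        {"participant": groups, "condition": cond.astype(int), "y": y}
    )


def synthetic_feature_rows(
    n_nf: int,
    n_f: int,
    shift_sd: float,
    seed: int,
    participant: str = "P01",
    latent_dim: int = 8,
) -> pd.DataFrame:
    """Feature-space stand-in table with realistic low-rank correlation.

    Stride features are highly redundant, so rows are built from
    ``latent_dim`` latent gaussian factors mapped through a fixed loading
    matrix plus small independent noise; F rows are displaced ``shift_sd``
    latent standard deviations along the first factor.  Useful for
    boundary/detector contracts without running the signal pipeline.
    """
    rng = np.random.default_rng(seed)
    cols = base_feature_columns()
    loadings = np.random.default_rng(1234).normal(size=(len(cols), latent_dim))
    loadings /= np.sqrt(latent_dim)
    z = rng.normal(size=(n_nf + n_f, latent_dim))
    z[n_nf:, 0] += shift_sd
    x = z @ loadings.T + 0.15 * rng.normal(size=(n_nf + n_f, len(cols)))
    table = pd.DataFrame(x, columns=cols)
    table.insert(0, "stride_index", np.arange(n_nf + n_f))
    table.insert(0, "condition", np.r_[np.zeros(n_nf), np.ones(n_f)].astype(int))
    table.insert(0, "participant", participant)
    return table
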