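"""Stride-to-stride variability and trajectory complexity per participant x state.

For one feature tracked across the ordered strides of a run, the trajectory
``{f_1, ..., f_M}`` is summarized by its mean, population variance,
coefficient of variation CV = sigma_f / mu_f, and sample entropy of the
stride-ordered sequence (trajectory SampEn, capturing run-level
irregularity trends on top of within-stride complexity).  Fatigued-minus-
non-fatigued deltas of CV and SampEn quantify how fatigue changes movement
variability for each runner.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import SampEnParams, sample_entropy

DEFAULT_FEATURES = ("acc_mag_rms", "gyro_mag_rms")

STATE_NAMES = {0: "NF", 1: "F"}


def trajectory_metrics(
    values: np.ndarray, sampen: SampEnParams = SampEnParams()
) -> dict[str, float]:
    """Mean, population variance, CV and trajectory SampEn of one feature sequence.

    A zero mean makes CV undefined (nan sentinel); SampEn needs at least
    m + 2 strides and is nan otherwise.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("trajectory needs at least 2 strides")
    mean = float(np.mean(x))
    var = float(np.mean((x - mean) ** 2))
    cv = float(np.sqrt(var) / mean) if mean != 0 else float("nan")
    if len(x) >= sampen.m + 2:
        se = sample_entropy(x, sampen)
    else:
        se = float("nan")
    return {"n_strides": len(x), "mean": mean, "var": var, "cv": cv, "sampen": se}


def variability_table(
    feature_table: pd.DataFrame,
    features: list[str] | tuple[str, ...] = DEFAULT_FEATURES,
    sampen: SampEnParams = SampEnParams(),
) -> pd.DataFrame:
    """One row per participant x state x feature, trajectories in stride order."""
    rows = []
    for (pid, cond), grp in feature_table.groupby(["participant", "condition"], sort=True):
        grp = grp.sort_values("stride_index")
        for feature in features:
            body = trajectory_metrics(grp[feature].to_numpy(float), sampen)
            rows.append(
                {"participant": pid, "state": STATE_NAMES[int(cond)], "feature": feature, **body}
            )
    return pd.DataFrame(rows)


def state_deltas(var_table: pd.DataFrame) -> pd.DataFrame:
    """F minus NF differences of CV and trajectory SampEn per participant x feature.

    Pairs missing one state are skipped with a warning.
    """
    rows = []
    for (pid, feature), grp in var_table.groupby(["participant", "feature"], sort=True):
        states = dict(zip(grp["state"], grp.index))
        if "NF" not in states or "F" not in states:
            warnings.warn(
                f"participant {pid}, feature {feature}: missing state, delta skipped",
                UserWarning,
            )
            continue
        f_row = grp.loc[states["F"]]
        nf_row = grp.loc[states["NF"]]
        rows.append(
            {
                "participant": pid,
                "feature": feature,
                "cv_f": float(f_row["cv"]),
                "cv_nf": float(nf_row["cv"]),
                "sampen_f": float(f_row["sampen"]),
                "sampen_nf": float(nf_row["sampen"]),
                "delta_cv": float(f_row["cv"] - nf_row["cv"]),
                "delta_sampen": float(f_row["sampen"] - nf_row["sampen"]),
            }
        )
    return pd.DataFrame(rows)
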