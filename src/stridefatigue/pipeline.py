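"""Configuration and end-to-end orchestration of the stride-fatigue pipeline.

Stages: simulate (or load recordings) -> segment -> features -> effects ->
global-eval -> personal-eval -> variability.  Every stage reads the previous
stage's CSV output and writes its own, so the stages compose identically to
one monolithic run.  All randomness funnels through a single seed, and the
resolved configuration is written next to the outputs of every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import personal, synth
from .features import BandSpec, SampEnParams, build_feature_table, feature_columns
from .global_models import MODEL_NAMES, lopo_splits, train_eval_feature_model
from .lmm import effects_table
from .preprocess import (
    FilterSpec,
    RawRecording,
    frame_to_windows,
    read_recording,
    segment_recording,
    windows_to_frame,
    write_recording,
)
from .variability import state_deltas, variability_table

log = logging.getLogger("stridefatigue")

ALL_STAGES = (
    "simulate",
    "segment",
    "features",
    "effects",
    "global-eval",
    "personal-eval",
    "variability",
)

DEFAULT_EFFECT_FEATURES = ("acc_mag_kurt", "acc_z_mean", "acc_y_max", "gyro_y_rms")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """Resolved run configuration; unknown keys are rejected on load."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    recordings_dir: str | None = None  # read real recordings instead of simulating
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    filter_order: int = 4
    filter_cutoff: float = 20.0
    n_points: int = 128
    sampen_m: int = 2
    sampen_r: float = 0.2
    bands: list = field(default_factory=lambda: [[0.5, 3.0], [3.0, 8.0], [8.0, 20.0]])
    feature_set: str = "base"  # "base" (64 moment features) or "extended"
    models: list = field(default_factory=lambda: list(MODEL_NAMES))
    effect_features: list = field(default_factory=lambda: list(DEFAULT_EFFECT_FEATURES))
    variability_features: list = field(default_factory=lambda: ["acc_mag_rms", "gyro_mag_rms"])
    k_folds: int = 5
    nu: float = 0.1

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.feature_set not in ("base", "extended"):
            raise ConfigError(f"feature_set must be 'base' or 'extended', got {cfg.feature_set!r}")
        bad = [m for m in cfg.models if m not in MODEL_NAMES]
        if bad:
            raise ConfigError(f"unknown model(s) {bad}; choose from {MODEL_NAMES}")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- derived specs ------------------------------------------------------
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order, cutoff=self.filter_cutoff)

    def sampen_params(self) -> SampEnParams:
        return SampEnParams(m=self.sampen_m, r=self.sampen_r)

    def band_spec(self) -> BandSpec:
        return BandSpec(bands=tuple(tuple(b) for b in self.bands))

    def synth_config(self) -> synth.SynthConfig:
        kwargs = dict(self.synth)
        if "fatigue" in kwargs:
            kwargs["fatigue"] = synth.FatigueEffects(**kwargs["fatigue"])
        if "strides_per_condition" in kwargs:
            kwargs["strides_per_condition"] = tuple(kwargs["strides_per_condition"])
        kwargs.setdefault("seed", self.seed)
        return synth.SynthConfig(**kwargs)


# ---------------------------------------------------------------------------
# Stage implementations (each reads/writes CSVs under cfg.out_dir)


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream file {path}; run the {producer!r} stage first"
        )
    return path


def stage_simulate(cfg: PipelineConfig) -> list[RawRecording]:
    out = _out(cfg) / "recordings"
    out.mkdir(exist_ok=True)
    recordings, truth = synth.generate_cohort(cfg.synth_config())
    for rec in recordings:
        write_recording(rec, out / f"{rec.participant_id}_{rec.condition}.csv")
    events = {
        f"{pid}_{cond}": list(map(float, ev)) for (pid, cond), ev in truth.events.items()
    }
    (Path(_out(cfg)) / "ground_truth.json").write_text(
        json.dumps(
            {
                "intercepts": truth.intercepts,
                "stride_frequency": truth.stride_frequency,
                "events": events,
            },
            indent=1,
        )
    )
    log.info("simulate: %d recordings written", len(recordings))
    return recordings


def _load_recordings(cfg: PipelineConfig) -> list[RawRecording]:
    rec_dir = Path(cfg.recordings_dir) if cfg.recordings_dir else _out(cfg) / "recordings"
    _require(rec_dir, "simulate")
    paths = sorted(rec_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording CSVs found in {rec_dir}")
    return [read_recording(p) for p in paths]


def stage_segment(cfg: PipelineConfig) -> pd.DataFrame:
    recordings = _load_recordings(cfg)
    windows = []
    dropped = 0
    for rec in recordings:
        w = segment_recording(rec, cfg.filter_spec(), n_points=cfg.n_points)
        if not w:
            dropped += 1
            log.warning("segment: recording %s/%s produced no strides", rec.participant_id, rec.condition)
        windows.extend(w)
    frame = windows_to_frame(windows)
    frame.to_csv(_out(cfg) / "stride_windows.csv", index=False)
    log.info("segment: %d strides from %d recordings (%d unsegmentable)", len(windows), len(recordings), dropped)
    return frame


def stage_features(cfg: PipelineConfig) -> pd.DataFrame:
    frame = pd.read_csv(_require(_out(cfg) / "stride_windows.csv", "segment"))
    windows = frame_to_windows(frame)
    table = build_feature_table(
        windows,
        sampen=cfg.sampen_params(),
        bands=cfg.band_spec(),
        include_extended=True,
    )
    table.to_csv(_out(cfg) / "features.csv", index=False)
    log.info("features: %d rows x %d columns", *table.shape)
    return table


def _read_features(cfg: PipelineConfig) -> pd.DataFrame:
    table = pd.read_csv(_require(_out(cfg) / "features.csv", "features"))
    for col in ("participant", "condition", "stride_index"):
        if col not in table.columns:
            raise ConfigError(f"feature table lacks required column {col!r}")
    return table


def stage_effects(cfg: PipelineConfig) -> pd.DataFrame:
    table = _read_features(cfg)
    effects, forest = effects_table(table, list(cfg.effect_features))
    effects.to_csv(_out(cfg) / "effects.csv", index=False)
    forest.to_csv(_out(cfg) / "forest.csv", index=False)
    log.info("effects: %d features fitted", len(effects))
    return effects


def stage_global_eval(cfg: PipelineConfig) -> pd.DataFrame:
    table = _read_features(cfg)
    folds = lopo_splits(table)
    summary_rows = []
    for model in cfg.models:
        result = train_eval_feature_model(
            table, model=model, feature_set=cfg.feature_set, seed=cfg.seed, folds=folds
        )
        result.per_participant.to_csv(_out(cfg) / f"lopo_{model}.csv", index=False)
        if result.importances is not None:
            result.importances.to_csv(_out(cfg) / f"importances_{model}.csv", index=False)
        summary_rows.append(
            {
                "model": model,
                "mean_accuracy": result.mean["accuracy"],
                "sd_accuracy": result.sd["accuracy"],
                "mean_f1": result.mean["f1"],
                "mean_auc": result.mean["auc"],
                "n_folds": len(result.per_participant),
            }
        )
        log.info("global-eval %s: mean LOPO accuracy %.4f", model, result.mean["accuracy"])
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(_out(cfg) / "lopo_summary.csv", index=False)
    return summary


def stage_personal_eval(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    table = _read_features(cfg)
    sup_results, anom_results = [], []
    skipped = 0
    for pid, sub in table.groupby("participant", sort=True):
        sub = sub.reset_index(drop=True)
        try:
            sup_results.append(personal.personal_supervised_cv(sub, k=cfg.k_folds, seed=cfg.seed))
            nf_rows = sub[sub["condition"] == 0]
            model = personal.fit_nf_ocsvm(nf_rows, nu=cfg.nu)
            anom_results.append(personal.evaluate_anomaly(model, sub))
        except ValueError as exc:
            skipped += 1
            log.warning("personal-eval: participant %s skipped (%s)", pid, exc)
    out = _out(cfg)
    frames = {}
    for name, results in (("supervised", sup_results), ("anomaly", anom_results)):
        per = personal.results_frame(results)
        per.to_csv(out / f"personal_{name}.csv", index=False)
        if len(per):
            summary = personal.aggregate_personal(per)
        else:
            log.warning("personal-eval: no %s results; empty summary written", name)
            summary = pd.DataFrame()
        summary.to_csv(out / f"personal_{name}_summary.csv")
        frames[name] = per
        frames[f"{name}_summary"] = summary
    log.info(
        "personal-eval: %d participants evaluated, %d skipped", len(sup_results), skipped
    )
    return frames


def stage_variability(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    table = _read_features(cfg)
    var_tab = variability_table(
        table, features=list(cfg.variability_features), sampen=cfg.sampen_params()
    )
    deltas = state_deltas(var_tab)
    var_tab.to_csv(_out(cfg) / "variability.csv", index=False)
    deltas.to_csv(_out(cfg) / "variability_deltas.csv", index=False)
    log.info("variability: %d records, %d deltas", len(var_tab), len(deltas))
    return {"records": var_tab, "deltas": deltas}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "features": stage_features,
    "effects": stage_effects,
    "global-eval": stage_global_eval,
    "personal-eval": stage_personal_eval,
    "variability": stage_variability,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the selected stages in canonical order, writing all table files.

    With no recordings directory configured, the simulate stage generates a
    synthetic cohort; otherwise simulate is skipped and recordings are read
    from disk.  Returns the per-stage in-memory outputs.
    """
    if stages is None:
        stages = list(ALL_STAGES)
    unknown = [s for s in stages if s not in STAGE_FUNCS]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; choose from {ALL_STAGES}")
    if cfg.recordings_dir is not None and "simulate" in stages:
        stages = [s for s in stages if s != "simulate"]

    out = _out(cfg)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    outputs = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        outputs[stage] = STAGE_FUNCS[stage](cfg)
    return outputs
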