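"""Shared configuration for the numbered analysis drivers (one seed, one output dir)."""

from pathlib import Path

from stridefatigue.pipeline import PipelineConfig

RESULTS_DIR = Path(__file__).resolve().parent.parent / "results" / "study"

CONFIG = PipelineConfig.from_dict({"out_dir": str(RESULTS_DIR), "seed": 20260923})
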