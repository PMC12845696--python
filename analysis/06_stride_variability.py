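"""Stride-to-stride variability and trajectory complexity, NF vs F.

Summarizes the acc_mag_rms and gyro_mag_rms trajectories per runner and
state by mean, variance, coefficient of variation, and trajectory sample
entropy, then reports the fatigued-minus-baseline deltas.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    out = run_pipeline(CONFIG, stages=["variability"])["variability"]
    deltas = out["deltas"]
    med = deltas.groupby("feature")[["delta_cv", "delta_sampen"]].median()
    print("cohort-median F - NF deltas:")
    print(med.to_string(float_format=lambda v: f"{v:+.4f}"))
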