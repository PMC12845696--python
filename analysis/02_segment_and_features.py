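"""Segment recordings into strides and build the per-stride feature table.

Filters each recording (4th-order zero-phase Butterworth, 20 Hz), derives
acceleration/angular-velocity magnitude channels, detects foot strikes in
the vertical acceleration, time-normalizes each stride to 128 points, and
extracts the 64 base moment features plus spectral and entropy extensions.
"""

import pandas as pd

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    run_pipeline(CONFIG, stages=["segment", "features"])
    table = pd.read_csv(f"{CONFIG.out_dir}/features.csv")
    n_nf = int((table["condition"] == 0).sum())
    n_f = int((table["condition"] == 1).sum())
    print(f"feature table: {table.shape[0]} strides ({n_nf} NF, {n_f} F), {table.shape[1] - 3} features")
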