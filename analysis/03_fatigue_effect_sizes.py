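"""Mixed-effects fatigue effects and standardized effect sizes.

Fits a participant-random-intercept model per headline feature
(acc_mag_kurt, acc_z_mean, acc_y_max, gyro_y_rms), reports the fatigue
coefficient with its Wald statistic and 95% CI, and derives Cohen's d,
Nakagawa-Schielzeth marginal/conditional R^2, and the partial R^2 of the
fatigue term.  Writes effects.csv and the forest-plot export.
"""

import pandas as pd

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    effects = run_pipeline(CONFIG, stages=["effects"])["effects"]
    cols = ["feature", "beta_fatigue", "z", "cohen_d", "r2_partial"]
    print(effects[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    signs = {f: ("-" if b < 0 else "+") for f, b in zip(effects["feature"], effects["beta_fatigue"])}
    print(f"effect directions recovered: {signs}")
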