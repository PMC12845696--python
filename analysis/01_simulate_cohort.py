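"""Simulate the synthetic running cohort.

Generates 19 runners, each with one non-fatigued (NF) and one fatigued (F)
400 m run segment at 256 Hz (50-80 strides per segment), with known
per-runner intercepts and configured fatigue effect directions, and writes
the recordings plus ground truth under results/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    recordings = run_pipeline(CONFIG, stages=["simulate"])["simulate"]
    n = sum(r.n_samples for r in recordings)
    print(f"wrote {len(recordings)} recordings ({n} samples total) to {CONFIG.out_dir}/recordings")
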