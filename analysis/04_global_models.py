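"""Population-level fatigue classifiers under leave-one-participant-out CV.

Trains random forest, RBF-SVM and gradient boosting on the pooled base-64
feature table, always testing on a runner excluded from training, and
exports per-participant accuracies, cohort summaries, and the ranked
random-forest feature importances.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    summary = run_pipeline(CONFIG, stages=["global-eval"])["global-eval"]
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    best = summary.loc[summary["mean_accuracy"].idxmax()]
    print(
        f"best global model: {best['model']} at mean LOPO accuracy "
        f"{best['mean_accuracy']:.3f} (SD {best['sd_accuracy']:.3f} across runners)"
    )
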