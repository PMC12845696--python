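"""Personalized fatigue detection: supervised RF and NF-only One-Class SVM.

For each runner, (1) a random forest cross-validated on that runner's own
labeled strides (stratified K-fold), and (2) a One-Class SVM fitted on the
runner's non-fatigued strides only and asked to flag fatigued strides as
anomalies.  Exports per-participant tables and cohort summaries.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CONFIG
from stridefatigue.pipeline import run_pipeline

if __name__ == "__main__":
    frames = run_pipeline(CONFIG, stages=["personal-eval"])["personal-eval"]
    sup = frames["supervised_summary"]
    anom = frames["anomaly_summary"]
    print("supervised personalized RF (cohort summary):")
    print(sup[["accuracy", "f1", "auc"]].to_string(float_format=lambda v: f"{v:.4f}"))
    print("NF-only One-Class SVM (cohort summary):")
    print(anom[["accuracy", "auc", "recall_f", "fpr_nf"]].to_string(float_format=lambda v: f"{v:.4f}"))
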