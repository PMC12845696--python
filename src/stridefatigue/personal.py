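"""Per-participant supervised classification and NF-only anomaly detection.

The supervised route trains a random forest on one runner's own labeled
strides under stratified K-fold cross-validation.  The anomaly route fits a
One-Class SVM on that runner's non-fatigued strides only — the model never
sees a fatigued stride during fitting — and scores every stride against the
learned baseline boundary, so fatigued strides surface as deviations from
the individual's normal movement pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .features import feature_columns
from .global_models import auc_rank


@dataclass
class PersonalSupervisedResult:
    participant: str
    n_strides: int
    n_f: int
    n_nf: int
    accuracy: float
    f1: float
    auc: float


@dataclass
class PersonalAnomalyResult:
    participant: str
    n_strides: int
    n_f: int
    n_nf: int
    accuracy: float
    f1: float
    auc: float
    recall_f: float
    fpr_nf: float


@dataclass
class NfAnomalyModel:
    """A fitted NF-baseline boundary together with its NF-only scaler."""

    scaler: StandardScaler
    svm: OneClassSVM
    columns: list[str] = field(default_factory=list)

    def anomaly_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous scores, higher = more anomalous (more fatigue-like)."""
        x = self.scaler.transform(table[self.columns].to_numpy(float))
        return -self.svm.decision_function(x)

    def predict_anomaly(self, table: pd.DataFrame) -> np.ndarray:
        """Binary anomaly labels at the boundary's native zero level."""
        return self.anomaly_scores(table) > 0


def personal_supervised_cv(
    table: pd.DataFrame, k: int = 5, seed: int = 0
) -> PersonalSupervisedResult:
    """Stratified K-fold random forest on one participant's strides.

    Requires both conditions present; if a class has fewer members than K,
    K is reduced with a warning (floor 2).  Metrics are averaged over folds.
    """
    pid = _single_participant(table)
    y = table["condition"].to_numpy(int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError(f"participant {pid}: both NF and F strides are required")
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(
            f"participant {pid}: class with {counts.min()} strides; K reduced to {k_eff}",
            UserWarning,
        )
    k_eff = max(2, k_eff)
    cols = feature_columns(table)
    x = table[cols].to_numpy(float)

    accs, f1s, aucs = [], [], []
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        scaler = StandardScaler().fit(x[train])
        clf = RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
        clf.fit(scaler.transform(x[train]), y[train])
        x_test = scaler.transform(x[test])
        pred = clf.predict(x_test)
        scores = clf.predict_proba(x_test)[:, 1]
        accs.append(np.mean(pred == y[test]))
        f1s.append(f1_score(y[test], pred, zero_division=0))
        aucs.append(auc_rank(scores[y[test] == 1], scores[y[test] == 0]))
    return PersonalSupervisedResult(
        participant=pid,
        n_strides=len(y),
        n_f=int(counts[1]),
        n_nf=int(counts[0]),
        accuracy=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        auc=float(np.nanmean(aucs)),
    )


def fit_nf_ocsvm(
    nf_table: pd.DataFrame, nu: float = 0.1, gamma: float | str = "scale"
) -> NfAnomalyModel:
    """Fit the NF-baseline One-Class SVM on non-fatigued strides only.

    Rows are standardized with NF-only statistics (the fatigued distribution
    must not leak into the baseline).  ``nu`` bounds the training outlier
    fraction, so scoring the training rows returns an inlier fraction of
    about ``1 - nu``.  Fewer than 20 NF strides is refused: the baseline
    boundary would be unreliable, collect more non-fatigued data.
    """
    if (nf_table["condition"].to_numpy(int) != 0).any():
        raise ValueError("fit_nf_ocsvm must only ever see NF (condition 0) strides")
    if len(nf_table) < 20:
        raise ValueError(
            f"only {len(nf_table)} NF strides; at least 20 are needed for a stable baseline"
        )
    cols = feature_columns(nf_table)
    x = nf_table[cols].to_numpy(float)
    scaler = StandardScaler().fit(x)
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    svm.fit(scaler.transform(x))
    return NfAnomalyModel(scaler=scaler, svm=svm, columns=cols)


def evaluate_anomaly(model: NfAnomalyModel, table: pd.DataFrame) -> PersonalAnomalyResult:
    """Score all strides of one participant against the NF baseline.

    Anomaly (predicted fatigue) is the positive class: recall on F is the
    fraction of fatigued strides flagged, FPR on NF the fraction of
    non-fatigued strides wrongly flagged, and AUC ranks the continuous
    anomaly scores.
    """
    pid = _single_participant(table)
    y = table["condition"].to_numpy(int)
    scores = model.anomaly_scores(table)
    pred = model.predict_anomaly(table).astype(int)
    n_f = int((y == 1).sum())
    n_nf = int((y == 0).sum())
    return PersonalAnomalyResult(
        participant=pid,
        n_strides=len(y),
        n_f=n_f,
        n_nf=n_nf,
        accuracy=float(np.mean(pred == y)),
        f1=float(f1_score(y, pred, zero_division=0)),
        auc=auc_rank(scores[y == 1], scores[y == 0]),
        recall_f=float(np.mean(pred[y == 1])) if n_f else float("nan"),
        fpr_nf=float(np.mean(pred[y == 0])) if n_nf else float("nan"),
    )


def aggregate_personal(per_participant: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Cohort summary (mean, SD, min, max) over per-participant metric columns."""
    if len(per_participant) < 1:
        raise ValueError("need at least one per-participant result")
    if metrics is None:
        metrics = [
            c
            for c in per_participant.columns
            if c not in ("participant",) and pd.api.types.is_numeric_dtype(per_participant[c])
        ]
    rows = {
        "mean": per_participant[metrics].mean(),
        "sd": per_participant[metrics].std(ddof=1).fillna(0.0),
        "min": per_participant[metrics].min(),
        "max": per_participant[metrics].max(),
    }
    return pd.DataFrame(rows).T[metrics]


def results_frame(results: list) -> pd.DataFrame:
    """Dataclass results -> DataFrame with one row per participant."""
    return pd.DataFrame([vars(r) for r in results])


def _single_participant(table: pd.DataFrame) -> str:
    pids = pd.unique(table["participant"])
    if len(pids) != 1:
        raise ValueError("expected the strides of exactly one participant")
    return str(pids[0])
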