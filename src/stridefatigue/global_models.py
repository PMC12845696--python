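"""Population-level fatigue classification with leave-one-participant-out folds.

Every fold trains on the pooled strides of all participants except one and
tests on that held-out runner, so reported accuracy measures generalization
to an unseen individual.  Standardization statistics are always computed on
the train fold only, and the cohort-level metric is the arithmetic mean of
per-participant metrics (never stride-pooled accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns
from .preprocess import StrideWindow

MODEL_NAMES = ("random_forest", "rbf_svm", "gradient_boosting")


@dataclass
class LopoResult:
    model: str
    per_participant: pd.DataFrame  # participant, n_strides, accuracy, f1, auc
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    importances: pd.DataFrame | None = None


def lopo_splits(table: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """One fold per participant: (train row-positions, test row-positions, id).

    Test folds partition the table (pairwise disjoint, union exhaustive) and
    never share a participant with their train fold.
    """
    participants = table["participant"].to_numpy()
    ids = pd.unique(participants)
    if len(ids) < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    folds = []
    for pid in ids:
        test = np.flatnonzero(participants == pid)
        train = np.flatnonzero(participants != pid)
        folds.append((train, test, str(pid)))
    return folds


def auc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive score > random negative), ties 1/2."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([neg, pos]))
    pos_rank_sum = ranks[len(neg):].sum()
    return float((pos_rank_sum - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _median_distance_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth heuristic: gamma = 1 / (2 * median pairwise distance^2)."""
    sub = x if len(x) <= 200 else x[rng.choice(len(x), 200, replace=False)]
    diffs = sub[:, None, :] - sub[None, :, :]
    dists = np.sqrt((diffs**2).sum(-1))
    med = float(np.median(dists[np.triu_indices(len(sub), k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def _make_model(name: str, seed: int, x_train: np.ndarray):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if name == "rbf_svm":
        gamma = _median_distance_gamma(x_train, np.random.default_rng(seed))
        return SVC(C=1.0, kernel="rbf", gamma=gamma)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=200, learning_rate=0.1, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def train_eval_feature_model(
    table: pd.DataFrame,
    model: str = "random_forest",
    feature_set: str = "base",
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray, str]] | None = None,
) -> LopoResult:
    """LOPO evaluation of one feature-based classifier.

    Features are standardized inside each fold with train-fold statistics
    only.  A degenerate single-class train fold is skipped with a warning.
    Random-forest importances are averaged over folds and exported ranked.
    """
    if folds is None:
        folds = lopo_splits(table)
    cols = feature_columns(table, feature_set)
    x_all = table[cols].to_numpy(float)
    y_all = table["condition"].to_numpy(int)

    rows = []
    importance_sum = np.zeros(len(cols))
    importance_folds = 0
    for train, test, pid in folds:
        y_train = y_all[train]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {pid}: single-class train fold skipped", UserWarning)
            continue
        scaler = StandardScaler().fit(x_all[train])
        x_train = scaler.transform(x_all[train])
        x_test = scaler.transform(x_all[test])
        clf = _make_model(model, seed, x_train)
        clf.fit(x_train, y_train)
        y_pred = clf.predict(x_test)
        y_test = y_all[test]
        scores = _scores(clf, x_test)
        rows.append(
            {
                "participant": pid,
                "n_strides": len(test),
                "accuracy": float(np.mean(y_pred == y_test)),
                "f1": float(f1_score(y_test, y_pred, zero_division=0)),
                "auc": auc_rank(scores[y_test == 1], scores[y_test == 0]),
            }
        )
        if hasattr(clf, "feature_importances_"):
            importance_sum += clf.feature_importances_
            importance_folds += 1

    per = pd.DataFrame(rows)
    metrics = ("accuracy", "f1", "auc")
    result = LopoResult(
        model=model,
        per_participant=per,
        mean={m: float(per[m].mean()) for m in metrics},
        sd={m: float(per[m].std(ddof=1)) for m in metrics},
    )
    if importance_folds:
        imp = pd.DataFrame(
            {"feature": cols, "importance": importance_sum / importance_folds}
        ).sort_values("importance", ascending=False, ignore_index=True)
        result.importances = imp
    return result


def train_eval_cnn(
    windows: list[StrideWindow],
    folds: list[tuple[np.ndarray, np.ndarray, str]],
    config: dict | None = None,
) -> LopoResult | None:
    """Optional shallow 1D-CNN stage on raw stride tensors.

    Requires torch; when it is unavailable the stage is cleanly disabled
    (returns None with a warning) and the rest of the pipeline proceeds.
    The intended architecture is two convolution blocks (16 then 32 filters,
    kernels 7 and 5, ReLU, max-pool 2), global average pooling, and a single
    sigmoid output, trained with early stopping on a train-fold split.
    """
    try:
        import torch  # noqa: F401
    except ImportError:
        warnings.warn("torch not installed: 1D-CNN stage disabled", UserWarning)
        return None
    raise NotImplementedError(
        "1D-CNN training is only available when torch is installed; "
        "this build targets the feature-based models"
    )
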