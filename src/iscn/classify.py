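"""Individual-level linear-SVM classification of iSCN features.

Stratified k-fold cross-validation with fold-internal standardization,
pooled test-fold confusion metrics, ROC AUC from decision-function
scores, and feature-weight aggregation to region-level contributions.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE = "patient"


@dataclasses.dataclass
class ClassificationReport:
    task: str
    feature_set: str
    fold_accuracy: np.ndarray       # percent, one value per fold
    accuracy: float                 # pooled, percent
    sensitivity: float              # percent (patients correctly detected)
    specificity: float              # percent (controls correctly detected)
    auc: float
    ci95: tuple[float, float]       # mean +/- 1.96 SE of fold accuracies
    confusion: dict[str, int]       # tp, fn, tn, fp pooled over folds
    mean_abs_weight: pd.Series      # mean |w| per feature across folds

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fold_accuracy"] = self.fold_accuracy.tolist()
        d["mean_abs_weight"] = None  # serialized separately (one row per feature)
        d["ci95"] = list(self.ci95)
        return d


def svm_classify(
    features: pd.DataFrame,
    labels,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    task: str = "patient_vs_control",
    feature_set: str = "features",
) -> ClassificationReport:
    """Linear-SVM classification with stratified cross-validation.

    Features are standardized with training-fold statistics only (no
    leakage); test-fold predictions are pooled for accuracy, sensitivity
    and specificity; AUC comes from the pooled decision-function scores;
    the mean absolute weight of each feature across folds is retained
    for region mapping.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if POSITIVE not in classes:
        raise ValueError(f"positive class {POSITIVE!r} absent from labels")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(f"each class needs >= {folds} members, got {counts}")
    x = features.to_numpy(float)
    y_bin = (y == POSITIVE).astype(int)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y_bin)
    score = np.empty(len(y), dtype=float)
    fold_acc = []
    weights = np.zeros((folds, x.shape[1]))
    for f, (tr, te) in enumerate(skf.split(x, y_bin)):
        model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        model.fit(x[tr], y_bin[tr])
        pred[te] = model.predict(x[te])
        score[te] = model.decision_function(x[te])
        fold_acc.append(100.0 * (pred[te] == y_bin[te]).mean())
        weights[f] = np.abs(model.named_steps["svc"].coef_[0])

    tp = int(((pred == 1) & (y_bin == 1)).sum())
    fn = int(((pred == 0) & (y_bin == 1)).sum())
    tn = int(((pred == 0) & (y_bin == 0)).sum())
    fp = int(((pred == 1) & (y_bin == 0)).sum())
    fold_acc = np.array(fold_acc)
    se = fold_acc.std(ddof=1) / np.sqrt(folds)
    mean = fold_acc.mean()
    return ClassificationReport(
        task=task,
        feature_set=feature_set,
        fold_accuracy=fold_acc,
        accuracy=100.0 * (tp + tn) / len(y),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        auc=float(roc_auc_score(y_bin, score)),
        ci95=(mean - 1.96 * se, mean + 1.96 * se),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        mean_abs_weight=pd.Series(weights.mean(axis=0), index=features.columns),
    )


_NODAL_RE = re.compile(r"^(degree|betweenness|eigenvector)_auc_r(\d+)$")
_GLOBAL_RE = re.compile(r"^[a-z_]+_auc$")
_EDGE_RE = re.compile(r"^kls_r(\d+)_r(\d+)$")


def map_region_contributions(
    mean_abs_weight: pd.Series, feature_set: str, top: int = 10
) -> pd.DataFrame:
    """Aggregate mean-|w| feature weights to region scores; return top regions.

    topology mode: a region's score is the mean of the mean-|w| of its
    degree, betweenness and eigenvector AUC features (global-metric
    features are excluded from region mapping).  connectivity mode: the
    mean of mean-|w| over the R-1 edges incident to the region.  Ties
    rank by ascending region label.
    """
    scores: dict[int, list[float]] = {}
    for name, w in mean_abs_weight.items():
        if feature_set == "topology":
            m = _NODAL_RE.match(name)
            if m:
                scores.setdefault(int(m.group(2)), []).append(float(w))
            elif _GLOBAL_RE.match(name):
                continue  # global metrics carry no region
            else:
                raise ValueError(f"unparseable topology feature name: {name!r}")
        elif feature_set == "connectivity":
            m = _EDGE_RE.match(name)
            if not m:
                raise ValueError(f"unparseable connectivity feature name: {name!r}")
            for g in (1, 2):
                scores.setdefault(int(m.group(g)), []).append(float(w))
        else:
            raise ValueError(f"unknown feature_set {feature_set!r}")
    df = pd.DataFrame(
        {
            "region_id": list(scores),
            "score": [float(np.mean(v)) for v in scores.values()],
            "n_features": [len(v) for v in scores.values()],
        }
    ).sort_values(["score", "region_id"], ascending=[False, True], kind="mergesort")
    return df.head(top).reset_index(drop=True)
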