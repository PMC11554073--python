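"""Model evaluation: temporal split, repeated stratified CV, metrics.

The cohort is split 2:1 by operation date (earliest two thirds train). Model
selection statistics come from stratified 5-fold cross-validation repeated 10
times with fold assignments re-drawn each repeat; per-fold AUC, accuracy,
sensitivity, specificity and F1 are recorded, ROC curves are averaged
vertically on a fixed FPR grid, and paired model comparisons use the paired
t-test over the (repeat, fold) metric pairs (with the usual caveat that CV
folds are not independent samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

POSITIVE = 1  # label 1 = 6-month postoperative KPS < 70
METRICS = ("auc", "accuracy", "sensitivity", "specificity", "f1")


@dataclass
class CvReport:
    model_tag: str
    records: list[dict] = field(default_factory=list)  # one per (repeat, fold)
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def mean(self, metric: str = "auc") -> float:
        return float(np.mean([r[metric] for r in self.records]))

    def std(self, metric: str = "auc") -> float:
        return float(np.std([r[metric] for r in self.records], ddof=1))

    def series(self, metric: str = "auc") -> np.ndarray:
        return np.array([r[metric] for r in self.records])


def temporal_split(clinical: pd.DataFrame, ratio: tuple[int, int] = (2, 1)):
    """Split patient ids by operation date: earliest ceil(n*2/3) train, rest test.

    Ties at the boundary break deterministically by patient_id.
    """
    df = clinical[["patient_id", "operation_date"]].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df = df.sort_values(["operation_date", "patient_id"], kind="mergesort")
    n = len(df)
    n_train = int(np.ceil(n * ratio[0] / (ratio[0] + ratio[1])))
    ids = df["patient_id"].tolist()
    return ids[:n_train], ids[n_train:]


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """AUC (tie-aware rank statistic) plus confusion-matrix metrics at threshold."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = labels == POSITIVE
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(scores)  # midranks handle ties as 1/2
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    pred = scores >= threshold
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {"auc": float(auc), "accuracy": acc, "sensitivity": sens,
            "specificity": spec, "f1": f1, "threshold": threshold}


def repeated_cv(model_builder, X: np.ndarray, y: np.ndarray,
                folds: int = 5, repeats: int = 10, seed: int = 0,
                model_tag: str = "model") -> CvReport:
    """Stratified k-fold CV repeated with fresh fold draws each repeat.

    ``model_builder(X_tr, y_tr, fold_seed)`` must return an object accepted by
    :func:`kpsfusion.models.predict_proba`. Records ``folds * repeats``
    metric rows and keeps per-fold (label, score) pairs for ROC averaging.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError("too few examples in a class to stratify")
    from .models import predict_proba

    report = CvReport(model_tag=model_tag, seed=seed)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for k, (tr, va) in enumerate(skf.split(X, y)):
            model = model_builder(X[tr], y[tr], seed * 1000 + r * folds + k)
            scores = predict_proba(model, X[va])
            rec = compute_metrics(y[va], scores)
            rec.update(repeat=r, fold=k)
            report.records.append(rec)
            report.fold_scores.append((y[va], scores))
    return report


def roc_curve_points(labels: np.ndarray, scores: np.ndarray):
    """ROC polyline (fpr, tpr) with tied scores grouped, ending at (1,1)."""
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(np.asarray(labels, int), np.asarray(scores, float),
                            pos_label=POSITIVE)
    return fpr, tpr


def mean_roc_curve(fold_scores, n_grid: int = 101):
    """Vertical averaging of per-fold ROC curves on a fixed FPR grid."""
    if not fold_scores:
        raise ValueError("need at least one fold")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for labels, scores in fold_scores:
        fpr, tpr = roc_curve_points(labels, scores)
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return grid, mean_tpr


def paired_t_test(a, b):
    """Two-sided paired t-test; zero-variance differences flagged as a tie.

    Returns ``(t, p)``; ``(nan, 1.0)`` with a warning when every paired
    difference is identical (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired series must have equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("paired differences have zero variance; t undefined, "
                      "reporting p=1.0 (exact tie)" if np.allclose(d, 0)
                      else "paired differences are constant; t undefined")
        return float("nan"), 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)
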