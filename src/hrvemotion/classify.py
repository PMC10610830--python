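"""Multinomial logistic-regression classification of ALQ feature vectors.

Features are z-scored with training-set statistics only, then fit with an
L2-regularized multinomial logistic regression (lbfgs, tol 1e-6, up to
1000 iterations — deterministic for a fixed split). Reported metrics:
accuracy, macro F1, macro recall, macro specificity, macro one-vs-rest
AUC, and a row-normalized confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .io import ClassifierParams


@dataclass
class EvalReport:
    accuracy: float
    f1_macro: float
    recall_macro: float
    specificity_macro: float
    auc_macro: float
    classes: list[str]
    confusion: np.ndarray            # row-normalized over true classes
    seed: int = 0
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1_macro": self.f1_macro,
            "recall_macro": self.recall_macro,
            "specificity_macro": self.specificity_macro,
            "auc_macro": self.auc_macro,
            "classes": list(self.classes),
            "confusion": np.asarray(self.confusion).tolist(),
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def split_data(
    X: np.ndarray, y: np.ndarray, train_fraction: float = 0.8, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split, deterministic under the seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    return train_test_split(
        np.asarray(X), y, train_size=train_fraction, stratify=y, random_state=seed)


def _specificity_macro(cm: np.ndarray) -> float:
    """Mean over classes of TN / (TN + FP), from the raw confusion matrix."""
    total = cm.sum()
    specs = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        tn = total - tp - fp - fn
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    return float(np.mean(specs))


def train_and_evaluate(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray,
    params: ClassifierParams | None = None,
) -> EvalReport:
    """Fit the classifier on train, report test metrics."""
    params = params or ClassifierParams()
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    scaler = StandardScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Xte = scaler.transform(X_test)
    model = LogisticRegression(
        C=params.C, solver="lbfgs", max_iter=params.max_iter, tol=params.tol)
    model.fit(Xtr, y_train)
    y_pred = model.predict(Xte)
    proba = model.predict_proba(Xte)
    cm = confusion_matrix(y_test, y_pred, labels=classes)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm.astype(float), row_sums,
                        out=np.zeros(cm.shape, dtype=float),
                        where=row_sums > 0)
    present = np.isin(classes, np.unique(y_test))
    if classes.size == 2:
        auc = float(roc_auc_score(y_test, proba[:, 1]))
    else:
        auc = float(roc_auc_score(
            y_test, proba, multi_class="ovr", average="macro", labels=classes))
    return EvalReport(
        accuracy=float(np.mean(y_pred == y_test)),
        f1_macro=float(f1_score(y_test, y_pred, labels=classes[present],
                                average="macro", zero_division=0)),
        recall_macro=float(recall_score(y_test, y_pred, labels=classes[present],
                                        average="macro", zero_division=0)),
        specificity_macro=_specificity_macro(cm),
        auc_macro=auc,
        classes=[str(c) for c in classes],
        confusion=cm_norm,
        seed=params.seed,
        n_train=len(y_train),
        n_test=len(y_test),
    )


@dataclass
class KFoldReport:
    folds: list[EvalReport]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)


def kfold_report(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0,
    params: ClassifierParams | None = None,
) -> KFoldReport:
    """Stratified k-fold evaluation with box-whisker summaries per metric."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(X, y):
        reports.append(train_and_evaluate(
            np.asarray(X)[train_idx], y[train_idx],
            np.asarray(X)[test_idx], y[test_idx], params=params))
    metrics = ("accuracy", "f1_macro", "recall_macro", "specificity_macro",
               "auc_macro")
    summary = {}
    for m in metrics:
        vals = np.asarray([getattr(r, m) for r in reports])
        summary[m] = {
            "min": float(vals.min()),
            "q1": float(np.percentile(vals, 25)),
            "median": float(np.median(vals)),
            "q3": float(np.percentile(vals, 75)),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
        }
    return KFoldReport(folds=reports, summary=summary)
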