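"""The binary "carried" vs "ambulation" classifier.

An ensemble-of-trees (random forest) model over the 78 window features,
tuned by grid-search 10-fold cross-validation over the entire data set
and evaluated with leave-one-subject-out (LOSO) cross-validation: each
participant's windows form one held-out test fold, so the reported
metrics reflect generalization to unseen children rather than unseen
windows.

Note the tuning protocol deliberately reuses all windows (including each
LOSO fold's test windows) to pick hyperparameters; this mirrors common
practice in small activity-recognition studies but is a mild leakage
risk.  ``loso_evaluate(..., nested=True)`` re-tunes inside every training
fold instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core import AMBULATION_BEHAVIORS
from .features import FEATURE_NAMES

__all__ = [
    "CLASS_ORDER",
    "binarize_labels",
    "default_grid",
    "tune",
    "loso_evaluate",
    "importance_report",
    "ClassifierReport",
]

#: Row/column order of the confusion matrix and per-class metrics.
CLASS_ORDER = ("carried", "ambulation")


def binarize_labels(behavior: str) -> str:
    """Map one of the five window behaviors to its binary class."""
    if behavior == "carried":
        return "carried"
    if behavior in AMBULATION_BEHAVIORS:
        return "ambulation"
    raise ValueError(
        f"behavior {behavior!r} is not part of the carried-vs-ambulation task; "
        f"expected 'carried' or one of {AMBULATION_BEHAVIORS}"
    )


def default_grid() -> list[dict]:
    """The default hyperparameter grid (small and documented)."""
    grid = []
    for n_estimators, max_depth, min_samples_leaf in itertools.product(
        (100, 300), (None, 5, 10), (1, 5)
    ):
        grid.append({
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
        })
    return grid


def _model_size_key(params: dict) -> tuple:
    """Ordering for the smallest-model tie-break: fewer trees, shallower
    depth (None = unbounded sorts last), larger leaves first."""
    depth = params.get("max_depth")
    return (
        params.get("n_estimators", 0),
        float("inf") if depth is None else depth,
        -params.get("min_samples_leaf", 1),
    )


def _make_model(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def tune(
    features: pd.DataFrame,
    labels,
    grid: list[dict] | None = None,
    folds: int = 10,
    seed: int = 0,
    feature_columns: tuple[str, ...] = FEATURE_NAMES,
) -> dict:
    """Pick the grid point with the best mean stratified k-fold CV accuracy.

    Grid points are visited from smallest model to largest, and a later
    point replaces the incumbent only on strictly higher mean accuracy, so
    ties resolve to the smallest model.  Fully seeded and deterministic.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must contain at least one point")
    X = features[list(feature_columns)].to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need both classes present, got only {classes}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} windows; need >= folds ({folds})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    best_params: dict | None = None
    best_score = -np.inf
    for params in sorted(grid, key=_model_size_key):
        score = cross_val_score(_make_model(params, seed), X, y, cv=cv,
                                scoring="accuracy").mean()
        if score > best_score:
            best_score = score
            best_params = params
    return dict(best_params, cv_accuracy=float(best_score))


@dataclass
class ClassifierReport:
    """LOSO-pooled evaluation of the carried-vs-ambulation model."""

    confusion: np.ndarray  # 2x2 ints, rows=true, cols=predicted, CLASS_ORDER
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    macro_precision: float
    macro_recall: float
    f1: float  # macro-averaged
    importances: pd.Series  # sorted descending, sums to 1
    per_fold_accuracy: dict[str, float] = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_windows(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASS_ORDER),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "f1": self.f1,
            "per_fold_accuracy": self.per_fold_accuracy,
            "hyperparameters": {k: v for k, v in self.hyperparameters.items()},
            "seed": self.seed,
            "top_importances": self.importances.head(10).to_dict(),
        }


def loso_evaluate(
    features: pd.DataFrame,
    labels,
    subject_ids,
    hyperparameters: dict | None = None,
    seed: int = 0,
    feature_columns: tuple[str, ...] = FEATURE_NAMES,
    nested: bool = False,
    grid: list[dict] | None = None,
) -> ClassifierReport:
    """Leave-one-subject-out evaluation with pooled predictions.

    Every subject's windows are held out exactly once; the model is
    refit on the remaining subjects each fold.  Metrics are computed on
    the pooled out-of-fold predictions; feature importances come from a
    final fit on all data.  ``nested=True`` re-runs grid tuning within
    each training fold (leakage-free protocol).
    """
    y = np.asarray(labels)
    groups = np.asarray(subject_ids)
    X = features[list(feature_columns)].to_numpy(dtype=float)
    if len(X) != len(y) or len(y) != len(groups):
        raise ValueError("features, labels and subject_ids must align")
    subjects = pd.unique(groups)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if hyperparameters is None and not nested:
        hyperparameters = tune(features, y, grid=grid, seed=seed,
                               feature_columns=feature_columns)
    hp = {k: v for k, v in (hyperparameters or {}).items() if k != "cv_accuracy"}

    y_pred = np.empty(len(y), dtype=object)
    per_fold = {}
    for subject in subjects:
        test = groups == subject
        train = ~test
        if nested:
            fold_hp = tune(features.loc[train], y[train], grid=grid, seed=seed,
                           feature_columns=feature_columns)
            fold_params = {k: v for k, v in fold_hp.items() if k != "cv_accuracy"}
        else:
            fold_params = hp
        model = _make_model(fold_params, seed)
        model.fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        per_fold[str(subject)] = float(np.mean(y_pred[test] == y[test]))
    assert not any(p is None for p in y_pred), "every window must be predicted once"

    order = list(CLASS_ORDER)
    conf = confusion_matrix(y, y_pred.astype(str), labels=order)
    prec, rec, _, _ = precision_recall_fscore_support(
        y, y_pred.astype(str), labels=order, zero_division=0
    )
    _, _, f1_macro, _ = precision_recall_fscore_support(
        y, y_pred.astype(str), labels=order, average="macro", zero_division=0
    )
    final = _make_model(hp if not nested else {}, seed)
    final.fit(X, y)
    importances = importance_report(final, feature_columns)

    return ClassifierReport(
        confusion=conf,
        accuracy=float(np.mean(y_pred.astype(str) == y)),
        precision={c: float(p) for c, p in zip(order, prec)},
        recall={c: float(r) for c, r in zip(order, rec)},
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        f1=float(f1_macro),
        importances=importances,
        per_fold_accuracy=per_fold,
        hyperparameters=hp,
        seed=seed,
    )


def importance_report(
    model: RandomForestClassifier,
    feature_columns: tuple[str, ...] = FEATURE_NAMES,
) -> pd.Series:
    """Mean-decrease-in-impurity importances, normalized to sum to 1 and
    sorted descending."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    s = pd.Series(imp, index=list(feature_columns), name="importance")
    return s.sort_values(ascending=False, kind="mergesort")
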