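"""Stratified 10-fold cross-validation and the classifier sweep.

The default downstream classifier is a random forest (500 trees,
sqrt-feature splits).  Optional sweep backends mirror the comparison set
commonly used for this task — logistic regression, SVM, XGBoost, LightGBM,
CatBoost — and any backend that is not installed is skipped with a warning
rather than aborting the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import SVC

from .metrics import METRIC_COLUMNS, compute_metrics, confusion_from_predictions, curves

__all__ = ["CvPlan", "make_classifier", "cross_validate", "classifier_sweep",
           "available_classifiers"]


@dataclass
class CvPlan:
    """Fold assignment: a reproducible partition of all sample indices."""

    folds: int = 10
    seed: int = 0
    stratified: bool = True

    def assignments(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y).astype(int)
        cls = StratifiedKFold if self.stratified else KFold
        splitter = cls(n_splits=self.folds, shuffle=True, random_state=self.seed)
        fold_of = np.full(len(y), -1, dtype=int)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            fold_of[test_idx] = f
        return fold_of


def make_classifier(name: str, seed: int = 0):
    """Instantiate a sweep backend; raises ImportError if not installed."""
    name = name.lower()
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                      random_state=seed)
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "svm":
        return SVC(probability=False, random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=200, random_state=seed,
                             verbosity=0, eval_metric="logloss")
    if name == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(n_estimators=200, random_state=seed, verbose=-1)
    if name == "catboost":
        from catboost import CatBoostClassifier
        return CatBoostClassifier(iterations=200, random_seed=seed, verbose=0)
    raise ValueError(f"unknown classifier {name!r}")


SWEEP_ORDER = ["rf", "lr", "xgboost", "svm", "catboost", "lightgbm"]


def available_classifiers(names=SWEEP_ORDER) -> list[str]:
    out = []
    for name in names:
        try:
            make_classifier(name)
            out.append(name)
        except ImportError:
            warnings.warn(f"classifier backend {name!r} is not installed; skipping")
    return out


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def cross_validate(X: np.ndarray, y: np.ndarray, plan: CvPlan | None = None,
                   classifier: str = "rf", seed: int = 0,
                   literal: bool = False) -> pd.DataFrame:
    """Per-fold metric table plus a ``Mean`` row of column means.

    Columns: MCC, Acc, Sn, Sp, Prec, F1, AUC, AUPR.  AUC/AUPR use the
    classifier's positive-class scores on the held-out fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y")
    plan = plan or CvPlan(seed=seed)
    fold_of = plan.assignments(y)
    rows = []
    for f in range(plan.folds):
        test = fold_of == f
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(
                f"fold {f} is single-class; use a stratified plan")
        clf = make_classifier(classifier, seed=seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        m = compute_metrics(confusion_from_predictions(y[test], pred),
                            literal=literal)
        c = curves(_scores(clf, X[test]), y[test])
        m["AUC"], m["AUPR"] = c["auc"], c["aupr"]
        rows.append(pd.Series(m, name=f))
    report = pd.DataFrame(rows)[METRIC_COLUMNS]
    report.index.name = "Fold"
    report.loc["Mean"] = report.mean(axis=0)
    return report


def classifier_sweep(X: np.ndarray, y: np.ndarray, plan: CvPlan | None = None,
                     classifiers=None, seed: int = 0) -> pd.DataFrame:
    """Per-fold AUC, folds as rows and classifiers as columns (paired design).

    The same fold assignment is reused for every classifier; the RF column
    is always present.
    """
    plan = plan or CvPlan(seed=seed)
    names = available_classifiers(classifiers or SWEEP_ORDER)
    if "rf" not in names:
        names = ["rf", *names]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    fold_of = plan.assignments(y)
    table = pd.DataFrame(index=range(plan.folds), columns=names, dtype=float)
    table.index.name = "Fold"
    for name in names:
        for f in range(plan.folds):
            test = fold_of == f
            clf = make_classifier(name, seed=seed)
            clf.fit(X[~test], y[~test])
            table.loc[f, name] = curves(_scores(clf, X[test]), y[test])["auc"]
    return table
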