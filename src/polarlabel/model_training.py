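"""Classifier training on gold or silver labels, plus the dx-code baseline.

Two model families are supported, with the study protocol's hyperparameters:

* random forest — 1000 trees, Gini impurity splits, remaining settings at
  the common defaults (unlimited depth, sqrt features per split, bootstrap);
* L2-penalized logistic regression — regularization strength selected by
  stratified 5-fold cross-validation maximizing AUROC over a 9-point
  logarithmic grid spanning 1e-4..1e4, optimizer capped at 10 000
  iterations.

Features are raw counts; no scaling is applied anywhere. The baseline is
the rule "predict the disease iff its diagnostic code appears at least
once".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .cohort_model import DiseaseCountVector
from .errors import DegenerateLabelsError
from .feature_extraction import FeatureMatrix

__all__ = [
    "TrainedModel",
    "train_random_forest",
    "train_logistic",
    "train_model",
    "dx_code_baseline",
    "LR_C_GRID",
]

LR_C_GRID = np.logspace(-4, 4, 9)


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier bound to the feature columns it was trained on."""

    kind: str  # "random_forest" | "logistic_regression"
    estimator: object
    feature_names: list[str]
    training_label_source: str = "unspecified"  # "gold" | "silver"

    def score(self, X: FeatureMatrix, patients: Sequence[str] | None = None) -> np.ndarray:
        """Predicted class-1 probabilities, one per patient row."""
        if X.feature_names != self.feature_names:
            raise ValueError("feature columns differ from those the model was trained on")
        mat = X.values if patients is None else X.values_for(patients)
        return self.estimator.predict_proba(mat)[:, 1]


def _check_labels(y: np.ndarray, minimum_per_class: int = 2) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelsError(
            f"training labels contain a single class ({classes.tolist()})"
        )
    if counts.min() < minimum_per_class:
        raise DegenerateLabelsError(
            f"need >= {minimum_per_class} examples per class, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )


def train_random_forest(X: FeatureMatrix, y: Sequence[int], seed: int,
                        label_source: str = "unspecified",
                        n_estimators: int = 1000) -> TrainedModel:
    """Fit the protocol's random forest (1000 Gini trees by default)."""
    y = np.asarray(y, dtype=np.int64)
    _check_labels(y)
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X.values, y)
    return TrainedModel("random_forest", rf, X.feature_names, label_source)


def train_logistic(X: FeatureMatrix, y: Sequence[int], seed: int,
                   label_source: str = "unspecified") -> TrainedModel:
    """Fit L2 logistic regression with its strength chosen by 5-fold CV.

    Folds are stratified; each fold must contain both classes, which
    requires at least 10 examples with >= 5 per class.
    """
    y = np.asarray(y, dtype=np.int64)
    _check_labels(y, minimum_per_class=5)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    # newton-cholesky: exact Hessian solves, fast and stable for the tall
    # thin unscaled count matrices this package produces (n >> d);
    # l1_ratios=(0.0,) is the ridge penalty in the current sklearn API
    lr = LogisticRegressionCV(
        Cs=LR_C_GRID,
        l1_ratios=(0.0,),
        scoring="roc_auc",
        cv=cv,
        solver="newton-cholesky",
        max_iter=10_000,
        random_state=seed,
        n_jobs=1,
        use_legacy_attributes=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lr.fit(X.values, y)
    return TrainedModel("logistic_regression", lr, X.feature_names, label_source)


def train_model(kind: str, X: FeatureMatrix, y: Sequence[int], seed: int,
                label_source: str = "unspecified",
                rf_n_estimators: int = 1000) -> TrainedModel:
    if kind in ("rf", "random_forest"):
        return train_random_forest(X, y, seed, label_source, n_estimators=rf_n_estimators)
    if kind in ("lr", "logistic_regression"):
        return train_logistic(X, y, seed, label_source)
    raise ValueError(f"unknown model kind {kind!r}")


def dx_code_baseline(counts: DiseaseCountVector) -> np.ndarray:
    """Score 1 iff the disease's diagnostic code is present, else 0."""
    return (counts.counts.to_numpy() >= 1).astype(np.float64)
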