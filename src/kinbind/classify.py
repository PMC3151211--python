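"""Preprocessing and classifier wrappers.

Nominal features are turned into binary indicators (a two-category column
becomes one 0/1 column, a k>2-category column becomes k indicators) and all
numeric features are min-max rescaled to [0, 1] using training statistics
only.  Two learners are wrapped: a pruned decision tree standing in for
C4.5/C5-style learning, and an SVM with linear, quadratic (polynomial degree
2) or RBF kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import FeatureColumn, FeatureTable, ValidationError


@dataclass
class ClassifierSpec:
    """Which learner to run and with what options."""

    kind: str = "tree"                 # "tree" | "svm"
    kernel: str = "quadratic"          # svm only: linear | quadratic | rbf
    C: float = 1.0
    pruning_confidence: float = 0.25   # tree only; mapped to cost-complexity
    min_leaf: int = 2
    global_pruning: bool = False
    ccp_alpha: float = 0.01            # cost-complexity stand-in for CF pruning
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("tree", "svm"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "svm" and self.kernel not in ("linear", "quadratic", "rbf"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValidationError("C must be positive")


def encode_nominal(table: FeatureTable) -> FeatureTable:
    """Binary-indicator encoding of nominal columns; numeric columns pass through.

    A value outside the column's known category set encodes as all-zero
    indicators (with a warning) rather than failing at transform time.
    """
    cols: list[FeatureColumn] = []
    arrays: list[np.ndarray] = []
    for c in table.columns:
        series = table.data[c.name]
        if c.kind == "numeric":
            cols.append(replace(c))
            arrays.append(series.to_numpy(dtype=float).reshape(-1, 1))
            continue
        cats = list(c.categories)
        observed = set(map(str, pd.unique(series)))
        unseen = observed - set(cats)
        if unseen:
            warnings.warn(
                f"column {c.name!r}: unseen categories {sorted(unseen)} encode as all-zero"
            )
        vals = series.astype(str).to_numpy()
        if len(cats) == 2:
            cols.append(
                FeatureColumn(f"{c.name}={cats[1]}", "numeric", c.group)
            )
            arrays.append((vals == cats[1]).astype(float).reshape(-1, 1))
        else:
            for cat in cats:
                cols.append(FeatureColumn(f"{c.name}={cat}", "numeric", c.group))
            arrays.append(
                np.stack([(vals == cat).astype(float) for cat in cats], axis=1)
            )
    data = np.concatenate(arrays, axis=1) if arrays else np.empty((len(table), 0))
    return FeatureTable(table.entity_ids, cols, data)


class MinMaxNormalizer:
    """[0, 1] rescaling fit on training rows; test values are clipped."""

    def __init__(self):
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        out = np.zeros_like(X)
        nonconst = span > 0
        out[:, nonconst] = (X[:, nonconst] - self.lo[nonconst]) / span[nonconst]
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def normalize(
    train: FeatureTable, test: FeatureTable | None = None
) -> tuple[FeatureTable, FeatureTable | None]:
    """Min-max normalize numeric columns; statistics come from ``train`` only."""
    numeric = [c.name for c in train.columns if c.kind == "numeric"]
    norm = MinMaxNormalizer().fit(train.data[numeric].to_numpy(dtype=float))

    def apply(t: FeatureTable) -> FeatureTable:
        data = t.data.copy()
        data[numeric] = norm.transform(data[numeric].to_numpy(dtype=float))
        return FeatureTable(t.entity_ids, [replace(c) for c in t.columns], data)

    return apply(train), (apply(test) if test is not None else None)


class FittedModel:
    """A trained classifier exposing labels plus signed decision scores."""

    def __init__(self, kind: str, model=None, constant: int | None = None):
        self.kind = kind
        self.model = model
        self.constant = constant

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = len(X)
        if self.constant is not None:
            score = 1.0 if self.constant == 1 else -1.0
            return np.full(n, self.constant, dtype=int), np.full(n, score)
        if self.kind == "tree":
            proba = self.model.predict_proba(X)[
                :, list(self.model.classes_).index(1)
            ]
            scores = proba - 0.5
            labels = (scores > 0).astype(int)
            # exact 0.5 leaves fall back to the tree's own vote
            ties = scores == 0
            if ties.any():
                labels[ties] = self.model.predict(X)[ties]
            return labels, scores
        scores = self.model.decision_function(X)
        return (scores > 0).astype(int), scores


def fit_model(
    spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray
) -> FittedModel:
    """Train the configured learner; deterministic under the spec's seed.

    A single-class training set yields a constant predictor with a warning.
    """
    y_train = np.asarray(y_train, dtype=int)
    classes = np.unique(y_train)
    if len(classes) == 1:
        warnings.warn("single-class training set: constant predictor")
        return FittedModel(spec.kind, constant=int(classes[0]))
    if spec.kind == "tree":
        from sklearn.tree import DecisionTreeClassifier

        clf = DecisionTreeClassifier(
            min_samples_leaf=spec.min_leaf,
            ccp_alpha=spec.ccp_alpha if not spec.global_pruning else spec.ccp_alpha * 2,
            random_state=spec.seed,
        )
        clf.fit(X_train, y_train)
        return FittedModel("tree", model=clf)
    from sklearn.svm import SVC

    kernel_args = {
        "linear": {"kernel": "linear"},
        "quadratic": {"kernel": "poly", "degree": 2, "gamma": "scale", "coef0": 1.0},
        "rbf": {"kernel": "rbf", "gamma": "scale"},
    }[spec.kernel]
    clf = SVC(C=spec.C, random_state=spec.seed, **kernel_args)
    clf.fit(X_train, y_train)
    return FittedModel("svm", model=clf)


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Train and predict in one call; returns (labels, signed scores)."""
    return fit_model(spec, X_train, y_train).predict(X_test)
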