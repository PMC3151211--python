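"""Dyadic leave-one-out evaluation for kinase-inhibitor pair prediction.

Predicting a pair admits four cold-start regimes, realized as LOOCV
variants over the m x n binding matrix (one split per pair):

* **hard**   — training holds no pair involving the test kinase or the test
  inhibitor: (m-1)(n-1) pairs; a double cold start.
* **soft**   — training holds everything except the tested pair: mn-1 pairs.
* **mixed**  — hard-case training plus an equal fraction of partner pairs for
  the test inhibitor (r_k kinase partners) and the test kinase (r_i
  inhibitor partners).
* **mixed-mixed** — like mixed but with unequal fractions/counts.

Metrics are the usual confusion-matrix ratios (accuracy, TPR, PPV, TNR,
NPV).  Two label-only baselines are provided: the majority-class predictor
and the probability-product rule that thresholds p_kin(binding) *
p_inh(binding) at an empirically optimized theta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import ClassifierSpec, MinMaxNormalizer, encode_nominal, fit_model
from .io import BindingMatrix, FeatureTable, ValidationError, pair_feature_table

CASES = ("hard", "soft", "mixed", "mixed_mixed")


class LeakageError(RuntimeError):
    """Test-pair information reached a training-side computation."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitSpec:
    """Which LOOCV variant to run.

    ``kinase_amount`` controls how many partner *kinases* are paired with the
    test inhibitor and inserted into training (a float fraction of m, or an
    absolute count <= m-1); ``inhibitor_amount`` likewise controls partner
    inhibitors for the test kinase (fraction of n, or count <= n-1).  The
    mixed case uses one equal fraction for both; mixed-mixed allows unequal
    amounts.
    """

    case: str = "soft"
    kinase_amount: float | int = 0
    inhibitor_amount: float | int = 0
    repeats: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.case not in CASES:
            raise ValidationError(f"unknown evaluation case {self.case!r}")
        if self.case == "mixed" and not (
            isinstance(self.kinase_amount, float)
            and isinstance(self.inhibitor_amount, float)
            and self.kinase_amount == self.inhibitor_amount
        ):
            raise ValidationError(
                "mixed case requires one equal fraction for both amounts"
            )
        if self.repeats is None:
            self.repeats = 10 if self.case in ("mixed", "mixed_mixed") else 1


@dataclass
class Split:
    """One LOOCV fold: a single test pair and its training pair set."""

    test: tuple[int, int]
    train: list[tuple[int, int]]


def _resolve_amount(amount: float | int, total: int, what: str) -> int:
    """Fraction -> round-half-up count clipped to total-1; absolute -> checked."""
    if isinstance(amount, float):
        if not (0.0 <= amount <= 1.0):
            raise ValidationError(f"{what} fraction must be in [0, 1]")
        return min(round_half_up(amount * total), total - 1)
    if not (0 <= amount <= total - 1):
        raise ValidationError(
            f"{what} absolute count {amount} exceeds the {total - 1} available pairs"
        )
    return int(amount)


def mixed_insertion_counts(m: int, n: int, spec: SplitSpec) -> tuple[int, int]:
    """(r_k, r_i): kinase-partner and inhibitor-partner pairs to insert."""
    r_k = _resolve_amount(spec.kinase_amount, m, "kinase_amount")
    r_i = _resolve_amount(spec.inhibitor_amount, n, "inhibitor_amount")
    return r_k, r_i


def make_splits(m: int, n: int, spec: SplitSpec, rng: np.random.Generator | None = None):
    """Yield one split per pair (m*n splits), row-major over (kinase, inhibitor)."""
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 kinases and 2 inhibitors")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.case in ("mixed", "mixed_mixed"):
        r_k, r_i = mixed_insertion_counts(m, n, spec)
    for ki in range(m):
        for ii in range(n):
            if spec.case == "soft":
                train = [
                    (a, b)
                    for a in range(m)
                    for b in range(n)
                    if (a, b) != (ki, ii)
                ]
            else:
                train = [
                    (a, b)
                    for a in range(m)
                    for b in range(n)
                    if a != ki and b != ii
                ]
                if spec.case in ("mixed", "mixed_mixed"):
                    other_kin = [a for a in range(m) if a != ki]
                    other_inh = [b for b in range(n) if b != ii]
                    ins_k = rng.choice(other_kin, size=r_k, replace=False)
                    ins_i = rng.choice(other_inh, size=r_i, replace=False)
                    train += [(int(a), ii) for a in ins_k]
                    train += [(ki, int(b)) for b in ins_i]
            yield Split(test=(ki, ii), train=train)


def restrict_to_test_molecules(split: Split) -> Split:
    """Keep only training pairs containing the test kinase or test inhibitor.

    Applied to a soft-case split this leaves (m-1) + (n-1) pairs.
    """
    ki, ii = split.test
    train = [(a, b) for a, b in split.train if a == ki or b == ii]
    return Split(test=split.test, train=train)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, y_true: int, y_pred: int) -> None:
        if y_true == 1:
            if y_pred == 1:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if y_pred == 1:
                self.fp += 1
            else:
                self.tn += 1


@dataclass
class MetricsReport:
    accuracy: float
    recall_pos: float | None   # TPR / sensitivity
    precision_pos: float | None  # PPV
    recall_neg: float | None   # TNR / specificity
    precision_neg: float | None  # NPV
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_pos": self.recall_pos,
            "precision_pos": self.precision_pos,
            "recall_neg": self.recall_neg,
            "precision_neg": self.precision_neg,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall and precision per class; zero-denominator ratios are absent."""
    if c.total == 0:
        raise ValidationError("no predictions to score")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        recall_pos=_ratio(c.tp, c.tp + c.fn),
        precision_pos=_ratio(c.tp, c.tp + c.fp),
        recall_neg=_ratio(c.tn, c.tn + c.fp),
        precision_neg=_ratio(c.tn, c.tn + c.fn),
        counts=c,
    )


# ---------------------------------------------------------------------------
# Baselines


def majority_baseline(train_labels) -> int:
    """The more frequent training class; an exact tie predicts no-binding."""
    labels = np.asarray(train_labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("empty training labels")
    pos = int(labels.sum())
    neg = labels.size - pos
    return 1 if pos > neg else 0


def _pair_probabilities(
    matrix: BindingMatrix, split: Split
) -> tuple[float, float]:
    ki, ii = split.test
    kin_pairs = [(a, b) for a, b in split.train if a == ki]
    inh_pairs = [(a, b) for a, b in split.train if b == ii]
    if not kin_pairs or not inh_pairs:
        raise ValidationError(
            "probability-product baseline is only possible in non-hard cases"
        )
    p_kin = float(np.mean([matrix.labels[a, b] for a, b in kin_pairs]))
    p_inh = float(np.mean([matrix.labels[a, b] for a, b in inh_pairs]))
    return p_kin, p_inh


def probability_product_baseline(
    matrix: BindingMatrix, split: Split, theta: float
) -> int:
    """Predict binding iff p_kin(b) * p_inh(b) > theta (strict)."""
    p_kin, p_inh = _pair_probabilities(matrix, split)
    return 1 if p_kin * p_inh > theta else 0


DEFAULT_THETA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))


def optimize_theta(
    matrix: BindingMatrix, splits: list[Split], grid=DEFAULT_THETA_GRID
) -> float:
    """theta maximizing baseline accuracy over the splits; ties pick the smallest."""
    if len(grid) == 0:
        raise ValidationError("empty theta grid")
    products = []
    for split in splits:
        p_kin, p_inh = _pair_probabilities(matrix, split)
        products.append((p_kin * p_inh, int(matrix.labels[split.test])))
    best_theta, best_acc = None, -1.0
    for theta in grid:
        acc = float(
            np.mean([(1 if prod > theta else 0) == label for prod, label in products])
        )
        if acc > best_acc:
            best_theta, best_acc = float(theta), acc
    return best_theta


# ---------------------------------------------------------------------------
# Random-feature ablation


def randomize_features(
    table: FeatureTable, groups, seed: int
) -> FeatureTable:
    """Replace numeric columns of the named groups by uniform random integers
    drawn within each column's observed [min, max] range."""
    groups = set(groups)
    present = set(c.group for c in table.columns)
    missing = groups - present
    if missing:
        raise ValidationError(f"groups {sorted(missing)} not in table")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    for c in table.columns:
        if c.group not in groups:
            continue
        if c.kind != "numeric":
            raise ValidationError(
                f"column {c.name!r} is nominal; randomization is defined for numeric scores"
            )
        col = data[c.name].to_numpy(dtype=float)
        lo, hi = int(np.floor(col.min())), int(np.ceil(col.max()))
        data[c.name] = rng.integers(lo, hi + 1, size=len(col)).astype(float)
    return FeatureTable(table.entity_ids, [replace(c) for c in table.columns], data)


# ---------------------------------------------------------------------------
# End-to-end experiment runner


@dataclass
class ExperimentReport:
    test: MetricsReport
    train: MetricsReport
    per_repeat_test: list[MetricsReport] = field(default_factory=list)

    @property
    def test_accuracy_mean(self) -> float:
        return float(np.mean([r.accuracy for r in self.per_repeat_test]))

    @property
    def test_accuracy_std(self) -> float:
        return float(np.std([r.accuracy for r in self.per_repeat_test]))


def _masked_matrix(matrix: BindingMatrix, train_set: set[tuple[int, int]]) -> BindingMatrix:
    """Binding matrix with every non-training label zeroed (training info only)."""
    labels = np.zeros_like(matrix.labels)
    for a, b in train_set:
        labels[a, b] = matrix.labels[a, b]
    return BindingMatrix(matrix.kinase_ids, matrix.inhibitor_ids, labels)


def run_experiment(
    matrix: BindingMatrix,
    kin_table: FeatureTable,
    inh_table: FeatureTable,
    split_spec: SplitSpec,
    clf_spec: ClassifierSpec,
    include_knn: bool = False,
    knn_k: int = 3,
    knn_metric: str = "tanimoto",
    restrict_training: bool = False,
    external: tuple[BindingMatrix, FeatureTable, FeatureTable] | None = None,
) -> ExperimentReport:
    """Per-split training and prediction with strict leakage control.

    KNN binding-profile features, normalization statistics and the classifier
    are computed from training information only; mixed cases are averaged
    over ``split_spec.repeats`` seeded runs.  ``restrict_training`` applies
    the test-molecule-only reduction to soft-case splits.  With ``external``
    the model is trained once on the full primary bundle and tested on every
    pair of the external bundle (hard-case semantics: the external molecules
    are unseen).
    """
    from .inhibitor_features import knn_binding_features

    if external is not None:
        return _external_experiment(
            matrix, kin_table, inh_table, clf_spec, external, include_knn
        )

    pair_table, labels, index_pairs = pair_feature_table(kin_table, inh_table, matrix)
    encoded = encode_nominal(pair_table)
    X_static = encoded.data.to_numpy(dtype=float)
    m, n = matrix.m, matrix.n
    pair_row = {p: r for r, p in enumerate(index_pairs)}

    if include_knn and split_spec.case == "hard":
        warnings.warn(
            "KNN binding-profile features are undefined in the hard case; "
            "the test inhibitor's profile is empty and its features are all zero"
        )

    per_repeat_test: list[MetricsReport] = []
    per_repeat_train: list[ConfusionCounts] = []
    for rep in range(split_spec.repeats):
        rng = np.random.default_rng((split_spec.seed + rep) % (2**31))
        test_counts = ConfusionCounts()
        train_counts = ConfusionCounts()
        for split in make_splits(m, n, split_spec, rng=rng):
            if restrict_training:
                split = restrict_to_test_molecules(split)
            train_set = set(split.train)
            if split.test in train_set:
                raise LeakageError("test pair found in training set")
            rows_train = np.array([pair_row[p] for p in split.train])
            row_test = pair_row[split.test]

            X_train = X_static[rows_train]
            X_test = X_static[row_test : row_test + 1]
            if include_knn:
                masked = _masked_matrix(matrix, train_set)
                if masked.labels[split.test] != 0:
                    raise LeakageError("test label leaked into masked matrix")
                knn = np.array(
                    [
                        knn_binding_features(masked, j, k=knn_k, metric=knn_metric)
                        for j in range(n)
                    ]
                )
                knn_train = knn[[b for _a, b in split.train]]
                knn_test = knn[[split.test[1]]]
                X_train = np.concatenate([X_train, knn_train], axis=1)
                X_test = np.concatenate([X_test, knn_test], axis=1)

            norm = MinMaxNormalizer().fit(X_train)
            X_train_n = norm.transform(X_train)
            X_test_n = norm.transform(X_test)
            y_train = labels[rows_train]

            model = fit_model(clf_spec, X_train_n, y_train)
            pred, _ = model.predict(X_test_n)
            test_counts.add(int(labels[row_test]), int(pred[0]))
            pred_train, _ = model.predict(X_train_n)
            for yt, yp in zip(y_train, pred_train):
                train_counts.add(int(yt), int(yp))
        per_repeat_test.append(compute_metrics(test_counts))
        per_repeat_train.append(train_counts)

    pooled_test = ConfusionCounts(
        tp=sum(r.counts.tp for r in per_repeat_test),
        fp=sum(r.counts.fp for r in per_repeat_test),
        tn=sum(r.counts.tn for r in per_repeat_test),
        fn=sum(r.counts.fn for r in per_repeat_test),
    )
    pooled_train = ConfusionCounts(
        tp=sum(c.tp for c in per_repeat_train),
        fp=sum(c.fp for c in per_repeat_train),
        tn=sum(c.tn for c in per_repeat_train),
        fn=sum(c.fn for c in per_repeat_train),
    )
    return ExperimentReport(
        test=compute_metrics(pooled_test),
        train=compute_metrics(pooled_train),
        per_repeat_test=per_repeat_test,
    )


def _external_experiment(
    matrix: BindingMatrix,
    kin_table: FeatureTable,
    inh_table: FeatureTable,
    clf_spec: ClassifierSpec,
    external: tuple[BindingMatrix, FeatureTable, FeatureTable],
    include_knn: bool,
) -> ExperimentReport:
    ext_matrix, ext_kin, ext_inh = external
    shared_kin = set(matrix.kinase_ids) & set(ext_matrix.kinase_ids)
    shared_inh = set(matrix.inhibitor_ids) & set(ext_matrix.inhibitor_ids)
    if shared_kin or shared_inh:
        raise LeakageError(
            "external test molecules overlap the training bundle: "
            f"{sorted(shared_kin | shared_inh)}"
        )
    if include_knn:
        warnings.warn(
            "KNN features are undefined for external (hard-case) molecules; zeroed"
        )
    train_table, y_train, _ = pair_feature_table(kin_table, inh_table, matrix)
    test_table, y_test, _ = pair_feature_table(ext_kin, ext_inh, ext_matrix)
    # encode with category sets taken from the union of both tables
    X_train = encode_nominal(train_table)
    X_test_df = encode_nominal(test_table)
    common = [c.name for c in X_train.columns if c.name in X_test_df.data.columns]
    Xtr = X_train.data[common].to_numpy(dtype=float)
    Xte = X_test_df.data[common].to_numpy(dtype=float)
    norm = MinMaxNormalizer().fit(Xtr)
    model = fit_model(clf_spec, norm.transform(Xtr), y_train)
    pred, _ = model.predict(norm.transform(Xte))
    test_counts = ConfusionCounts()
    for yt, yp in zip(y_test, pred):
        test_counts.add(int(yt), int(yp))
    pred_tr, _ = model.predict(norm.transform(Xtr))
    train_counts = ConfusionCounts()
    for yt, yp in zip(y_train, pred_tr):
        train_counts.add(int(yt), int(yp))
    test_report = compute_metrics(test_counts)
    return ExperimentReport(
        test=test_report,
        train=compute_metrics(train_counts),
        per_repeat_test=[test_report],
    )
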