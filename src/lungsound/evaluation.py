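"""Cross-validated evaluation: accuracy, sensitivity, specificity.

The abnormal class is positive. Per fold,

* CA  = (TP + TN) / (TP + TN + FP + FN) x 100
* SEN = TP / (TP + FN) x 100   (abnormal recall)
* SPE = TN / (TN + FP) x 100   (normal recall)

and the report averages the percentages over folds ("mean of fold
metrics"); pooled-count metrics over the union of test folds are also
emitted for transparency. The default split stratifies cycles by class.
Cycles from one subject can then land in both training and test folds —
faithful to evaluation on pooled cycles, but optimistic when subjects
differ systematically — so a subject-disjoint ``subject_grouped`` mode
is provided and recommended when subject identifiers exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classification import (
    FeatureScaler,
    elm_predict,
    elm_train,
    encode_labels,
    svm_predict,
    svm_train,
)
from .features import FEATURE_SETS, FeatureVector

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvaluationReport",
    "ClassifierSpec",
    "compute_metrics",
    "confusion_from_labels",
    "cross_validate",
    "features_to_matrix",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with abnormal as the positive class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            TP=self.TP + other.TP,
            TN=self.TN + other.TN,
            FP=self.FP + other.FP,
            FN=self.FN + other.FN,
        )


def compute_metrics(counts: ConfusionCounts):
    """(CA, SEN, SPE) percentages; a zero-denominator metric is None."""
    ca = 100.0 * (counts.TP + counts.TN) / counts.total if counts.total else None
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    sen = 100.0 * counts.TP / pos if pos else None
    spe = 100.0 * counts.TN / neg if neg else None
    return ca, sen, spe


def confusion_from_labels(true_pm1, predicted_pm1) -> ConfusionCounts:
    """Confusion counts from +/-1 encoded true and predicted labels."""
    t = np.asarray(true_pm1)
    p = np.asarray(predicted_pm1)
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    return ConfusionCounts(
        TP=int(np.sum((t > 0) & (p > 0))),
        TN=int(np.sum((t < 0) & (p < 0))),
        FP=int(np.sum((t < 0) & (p > 0))),
        FN=int(np.sum((t > 0) & (p < 0))),
    )


@dataclass(frozen=True)
class FoldResult:
    fold: int
    counts: ConfusionCounts
    CA: float | None
    SEN: float | None
    SPE: float | None


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and with what hyperparameters."""

    kind: str = "elm"  # {"elm", "svm"}
    n_hidden: int = 10
    C: float = 1.0
    gamma: object = "scale"

    def train(self, X, d, seed: int):
        if self.kind == "elm":
            return elm_train(X, d, n_hidden=self.n_hidden, rng_seed=seed)
        if self.kind == "svm":
            return svm_train(X, d, C=self.C, gamma=self.gamma)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def predict(self, model, X):
        if self.kind == "elm":
            return elm_predict(model, X)
        return svm_predict(model, X)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and averaged cross-validation metrics."""

    per_fold: tuple
    mean_CA: float
    mean_SEN: float
    mean_SPE: float
    pooled: ConfusionCounts
    pooled_CA: float | None
    pooled_SEN: float | None
    pooled_SPE: float | None
    feature_set: str
    classifier: str
    seed: int
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "classifier": self.classifier,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "mean_CA": self.mean_CA,
            "mean_SEN": self.mean_SEN,
            "mean_SPE": self.mean_SPE,
            "pooled_CA": self.pooled_CA,
            "pooled_SEN": self.pooled_SEN,
            "pooled_SPE": self.pooled_SPE,
            "pooled_counts": asdict(self.pooled),
            "per_fold": [
                {
                    "fold": f.fold,
                    "counts": asdict(f.counts),
                    "CA": f.CA,
                    "SEN": f.SEN,
                    "SPE": f.SPE,
                }
                for f in self.per_fold
            ],
        }

    def summary(self) -> str:
        lines = [
            f"{self.classifier.upper()} on {self.feature_set} "
            f"({self.n_folds}-fold, seed {self.seed})",
            f"{'fold':>4} {'TP':>4} {'TN':>4} {'FP':>4} {'FN':>4} "
            f"{'CA%':>7} {'SEN%':>7} {'SPE%':>7}",
        ]
        def _fmt(v):
            return f"{v:7.2f}" if v is not None else "   n/a "
        for f in self.per_fold:
            c = f.counts
            lines.append(
                f"{f.fold:>4} {c.TP:>4} {c.TN:>4} {c.FP:>4} {c.FN:>4} "
                f"{_fmt(f.CA)} {_fmt(f.SEN)} {_fmt(f.SPE)}"
            )
        lines.append(
            f"mean{'':>24} {self.mean_CA:7.2f} {self.mean_SEN:7.2f} "
            f"{self.mean_SPE:7.2f}"
        )
        return "\n".join(lines)


def features_to_matrix(features, feature_set: str | None = None):
    """Stack FeatureVectors into (X, encoded targets, subjects)."""
    if not features:
        raise ValueError("empty feature list")
    fs = feature_set or features[0].feature_set
    cols = FEATURE_SETS[fs]
    X = np.array(
        [
            [np.nan if getattr(f, c) is None else getattr(f, c) for c in cols]
            for f in features
        ],
        dtype=np.float64,
    )
    if np.any(np.isnan(X)):
        raise ValueError(
            f"feature set {fs!r} requires fields that are unset in the input"
        )
    d = encode_labels([f.label for f in features])
    subjects = np.array([f.source for f in features])
    return X, d, subjects


def _grouped_folds(subjects: np.ndarray, n_folds: int, seed: int):
    """Subject-disjoint folds, subjects shuffled deterministically."""
    uniq = np.unique(subjects)
    if uniq.size < n_folds:
        raise ValueError(
            f"subject_grouped needs >= {n_folds} subjects, got {uniq.size}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    assignment = {s: i % n_folds for i, s in enumerate(order)}
    fold_of = np.array([assignment[s] for s in subjects])
    for k in range(n_folds):
        test = np.nonzero(fold_of == k)[0]
        train = np.nonzero(fold_of != k)[0]
        yield train, test


def cross_validate(
    features,
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    n_folds: int = 5,
    split_mode: str = "cycle_stratified",
    seed: int = 0,
    feature_set: str | None = None,
) -> EvaluationReport:
    """K-fold cross-validation with leakage-free standardisation.

    Folds are class-stratified over cycles (default) or subject-disjoint;
    the feature scaler and the classifier are fit on the training folds
    only. Deterministic given ``seed``: the same seed drives the fold
    shuffle and the ELM hidden-layer draw.
    """
    X, d, subjects = features_to_matrix(features, feature_set)
    fs = feature_set or features[0].feature_set

    if split_mode == "cycle_stratified":
        for cls in (-1.0, 1.0):
            n_cls = int(np.sum(d == cls))
            if n_cls < n_folds:
                raise ValueError(
                    f"cycle_stratified needs >= {n_folds} samples per class, "
                    f"class {cls:+.0f} has {n_cls}"
                )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = splitter.split(X, d)
    elif split_mode == "subject_grouped":
        folds = _grouped_folds(subjects, n_folds, seed)
    else:
        raise ValueError(f"unknown split_mode {split_mode!r}")

    per_fold = []
    pooled = ConfusionCounts()
    for k, (train_idx, test_idx) in enumerate(folds):
        scaler = FeatureScaler.fit(X[train_idx])
        model = classifier_spec.train(
            scaler.transform(X[train_idx]), d[train_idx], seed=seed + k
        )
        pred, _ = classifier_spec.predict(model, scaler.transform(X[test_idx]))
        counts = confusion_from_labels(d[test_idx], pred)
        ca, sen, spe = compute_metrics(counts)
        per_fold.append(FoldResult(fold=k, counts=counts, CA=ca, SEN=sen, SPE=spe))
        pooled = pooled + counts

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    pca, psen, pspe = compute_metrics(pooled)
    return EvaluationReport(
        per_fold=tuple(per_fold),
        mean_CA=_mean([f.CA for f in per_fold]),
        mean_SEN=_mean([f.SEN for f in per_fold]),
        mean_SPE=_mean([f.SPE for f in per_fold]),
        pooled=pooled,
        pooled_CA=pca,
        pooled_SEN=psen,
        pooled_SPE=pspe,
        feature_set=fs,
        classifier=classifier_spec.kind,
        seed=seed,
        n_folds=n_folds,
    )
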