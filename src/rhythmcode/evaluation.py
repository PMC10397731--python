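"""Leave-one-trial-out evaluation of scalar code-count features.

Every (channel, code) feature is a single count per trial.  Each trial is
held out once; the classifier is fit on the remaining trials (features
standardised by training-fold statistics only) and scored on the held-out
trial.  Four classifier families are supported: k-NN, RBF-kernel SVM
(one-vs-one for multiclass), LDA (one-vs-one for multiclass) and
multinomial logistic regression.

All predictions are deterministic.  Degenerate folds — a single class in
the training fold, or a zero-variance feature — fall back to the
training-fold majority label (ties to the lowest class index), except for
k-NN where all-equal distances are treated as a tied vote resolved to the
lowest class index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsOneClassifier
from sklearn.svm import SVC

from .errors import InvalidInputError, InvalidSpecError, TooFewTrialsError
from .rhythm_codes import FeatureTable

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "AccuracyRecord",
    "loto_folds",
    "fit_predict",
    "loto_cv_accuracy",
    "evaluate_table",
    "majority_vote_all_features",
    "records_to_frame",
]

CLASSIFIER_KINDS = ("knn", "svm_rbf", "lda", "logreg")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration.

    ``k`` applies to k-NN only and must be a positive odd integer (the
    source designs use 5 for 40- and 45-trial sets and 3 for 20-trial
    sets).  ``C`` and ``gamma`` apply to the RBF SVM; ``gamma='scale'``
    means 1 / (n_features * training variance).
    """

    kind: str
    k: int = 5
    C: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise InvalidSpecError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )
        if self.kind == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise InvalidSpecError(f"k must be a positive odd integer, got {self.k}")
        if self.kind == "svm_rbf":
            if self.C <= 0:
                raise InvalidSpecError("C must be positive")
            if not (self.gamma == "scale" or (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
                raise InvalidSpecError("gamma must be positive or 'scale'")

    @staticmethod
    def default_k(n_trials: int) -> int:
        """Design-size default: 3 for 20-trial designs, else 5."""
        return 3 if n_trials <= 20 else 5


@dataclass(frozen=True)
class AccuracyRecord:
    """LOTO-CV outcome for one (channel, code, classifier) triple."""

    channel: str
    code: str
    classifier: str
    accuracy: float
    n_trials: int
    predictions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise InvalidInputError(f"accuracy must be in [0, 1], got {self.accuracy}")


def loto_folds(n_trials: int) -> list[tuple[np.ndarray, int]]:
    """Leave-one-trial-out folds: (training indices, held-out index) per trial."""
    if n_trials < 3:
        raise TooFewTrialsError(f"LOTO-CV needs at least 3 trials, got {n_trials}")
    idx = np.arange(n_trials)
    return [(np.delete(idx, i), i) for i in idx]


def _class_order(labels: Sequence[str]) -> list[str]:
    return sorted(set(labels))


def _majority(y_train: Sequence[str], classes: Sequence[str]) -> str:
    counts = {c: 0 for c in classes}
    for y in y_train:
        counts[y] += 1
    best = max(counts.values())
    # ties resolve to the lowest class index
    return next(c for c in classes if counts[c] == best)


def _knn_predict(
    x_train: np.ndarray, y_train: Sequence[str], x_test: float, k: int, classes: Sequence[str]
) -> str:
    """Scalar k-NN with pinned tie rules.

    Neighbour-vote ties break by smallest summed distance, then lowest
    class index; if every training point is equidistant the vote is a full
    tie and resolves to the lowest class index.
    """
    d = np.abs(x_train - x_test)
    if np.ptp(d) == 0:
        return classes[0]
    k = min(k, x_train.size)
    order = np.lexsort((np.arange(x_train.size), d))[:k]
    votes = {c: 0 for c in classes}
    dist_sum = {c: 0.0 for c in classes}
    for i in order:
        votes[y_train[i]] += 1
        dist_sum[y_train[i]] += d[i]
    best = max(votes.values())
    tied = [c for c in classes if votes[c] == best]
    if len(tied) == 1:
        return tied[0]
    min_sum = min(dist_sum[c] for c in tied)
    return next(c for c in tied if dist_sum[c] == min_sum)


def fit_predict(
    spec: ClassifierSpec,
    x_train: np.ndarray,
    y_train: Sequence[str],
    x_test: float,
    classes: Sequence[str] | None = None,
) -> str:
    """Train on the fold and predict the held-out scalar; fully deterministic."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = list(y_train)
    if classes is None:
        classes = _class_order(y_train)
    present = set(y_train)
    if len(present) < 2:
        warnings.warn(
            "training fold contains a single class; predicting it directly",
            stacklevel=2,
        )
        return y_train[0]
    mu, sd = x_train.mean(), x_train.std()
    if sd == 0.0:
        if spec.kind == "knn":
            return classes[0]  # all-equal distances: tied vote -> lowest class
        return _majority(y_train, classes)
    xs = (x_train - mu) / sd
    xt = (x_test - mu) / sd
    if spec.kind == "knn":
        return _knn_predict(xs, y_train, xt, spec.k, classes)
    X = xs[:, None]
    Xt = np.array([[xt]])
    if spec.kind == "svm_rbf":
        model = SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")  # OVO multiclass
    elif spec.kind == "lda":
        base = LinearDiscriminantAnalysis()
        model = OneVsOneClassifier(base) if len(present) > 2 else base
    elif spec.kind == "logreg":
        model = LogisticRegression(solver="lbfgs", tol=1e-8, max_iter=1000)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise InvalidSpecError(spec.kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model.fit(X, y_train)
            return str(model.predict(Xt)[0])
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("degenerate training fold; falling back to majority label")
            return _majority(y_train, classes)


def loto_cv_accuracy(
    values: np.ndarray,
    labels: Sequence[str],
    spec: ClassifierSpec,
    channel: str = "",
    code: str = "",
) -> AccuracyRecord:
    """LOTO-CV accuracy of one scalar feature: correct folds / n_trials.

    Folds whose held-out trial has an identical (value, label) pair reuse
    the cached prediction — the training multiset and test point are
    identical, so the outcome is too.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(labels) != values.size:
        raise InvalidInputError("one label per trial is required")
    classes = _class_order(labels)
    if len(classes) < 2:
        raise InvalidInputError("at least two classes are required for evaluation")
    folds = loto_folds(values.size)
    cache: dict[tuple[float, str], str] = {}
    predictions: list[str] = []
    correct = 0
    for train_idx, test_idx in folds:
        key = (values[test_idx], labels[test_idx])
        if key not in cache:
            cache[key] = fit_predict(
                spec,
                values[train_idx],
                [labels[i] for i in train_idx],
                values[test_idx],
                classes=classes,
            )
        pred = cache[key]
        predictions.append(pred)
        correct += pred == labels[test_idx]
    return AccuracyRecord(
        channel=channel,
        code=code,
        classifier=spec.kind,
        accuracy=correct / values.size,
        n_trials=values.size,
        predictions=tuple(predictions),
    )


def evaluate_table(
    table: FeatureTable,
    specs: Iterable[ClassifierSpec],
    channels: Sequence[str] | None = None,
) -> list[AccuracyRecord]:
    """Score every (channel, code) feature under every classifier spec."""
    labels = list(table.labels)
    arr = table.data.to_numpy()
    columns = list(table.data.columns)
    wanted = set(channels) if channels is not None else None
    records: list[AccuracyRecord] = []
    for spec in specs:
        for j, col in enumerate(columns):
            channel, code = col.split(":")
            if wanted is not None and channel not in wanted:
                continue
            records.append(
                loto_cv_accuracy(arr[:, j], labels, spec, channel=channel, code=code)
            )
    return records


def majority_vote_all_features(
    records: Sequence[AccuracyRecord], labels: Sequence[str]
) -> tuple[list[str], float]:
    """Per-trial modal prediction across all features; ties to lowest class.

    All records must carry fold predictions from identical LOTO folds.
    """
    if not records:
        raise InvalidInputError("at least one evaluated feature is required")
    n = len(labels)
    if any(len(r.predictions) != n for r in records):
        raise InvalidInputError("records must hold one prediction per trial")
    classes = _class_order(labels)
    preds: list[str] = []
    for t in range(n):
        counts = {c: 0 for c in classes}
        for r in records:
            counts[r.predictions[t]] += 1
        best = max(counts.values())
        preds.append(next(c for c in classes if counts[c] == best))
    accuracy = sum(p == y for p, y in zip(preds, labels)) / n
    return preds, accuracy


def records_to_frame(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Tabular dump: channel, code, classifier, accuracy, n_trials."""
    return pd.DataFrame(
        [
            {
                "channel": r.channel,
                "code": r.code,
                "classifier": r.classifier,
                "accuracy": r.accuracy,
                "n_trials": r.n_trials,
            }
            for r in records
        ]
    )
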