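"""Subject-disjoint evaluation protocol and the SVM classifier head.

Samples are split by SUBJECT into train/validation/test (default 70/20/10
with largest-remainder rounding over subject counts), repeated with fresh
random subject assignments (default 10 repeats); the headline number is the
mean test accuracy over repeats. Features are z-scored with statistics
fitted on the training rows only. The SVM head is an RBF-kernel SVC with a
(penalty C, kernel width gamma) grid selected on the validation split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "Split",
    "make_splits",
    "standardize",
    "Standardizer",
    "svm_train",
    "evaluate",
    "EvalReport",
    "aggregate_reports",
]


@dataclass
class SplitPlan:
    repeats: int = 10
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class Split:
    train: np.ndarray  # sample indices
    val: np.ndarray
    test: np.ndarray
    train_subjects: list[str]
    val_subjects: list[str]
    test_subjects: list[str]


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def make_splits(subjects: list[str], labels: list[str], plan: SplitPlan) -> list[Split]:
    """Per-repeat subject-disjoint index sets.

    Every sample follows its subject. If a class is entirely absent from a
    repeat's training rows the repeat is re-drawn (up to 100 times).
    """
    uniq: list[str] = []
    for s in subjects:
        if s not in uniq:
            uniq.append(s)
    if len(uniq) < 10:
        raise ValueError("need at least 10 subjects for the split protocol")
    n_tr, n_va, n_te = _largest_remainder(len(uniq), plan.fractions)
    if min(n_tr, n_va, n_te) < 1:
        raise ValueError("fractions leave an empty split")
    subjects_arr = np.asarray(subjects)
    labels_arr = np.asarray(labels)
    all_classes = set(labels)
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.repeats):
        for attempt in range(100):
            perm = rng.permutation(len(uniq))
            tr = [uniq[i] for i in perm[:n_tr]]
            va = [uniq[i] for i in perm[n_tr : n_tr + n_va]]
            te = [uniq[i] for i in perm[n_tr + n_va :]]
            tr_idx = np.flatnonzero(np.isin(subjects_arr, tr))
            if set(labels_arr[tr_idx]) == all_classes:
                break
        else:
            raise RuntimeError("could not draw a split with every class in training")
        splits.append(
            Split(
                train=tr_idx,
                val=np.flatnonzero(np.isin(subjects_arr, va)),
                test=np.flatnonzero(np.isin(subjects_arr, te)),
                train_subjects=tr,
                val_subjects=va,
                test_subjects=te,
            )
        )
    return splits


@dataclass
class Standardizer:
    """Per-dimension z-score transform fitted on training rows only.

    Dimensions with train std below 1e-12 pass through unscaled. The
    fingerprint records which rows the fit touched, as a leakage guard.
    """

    mean: np.ndarray
    std: np.ndarray
    fit_fingerprint: str

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def standardize(X: np.ndarray, fit_on: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Fit on ``X[fit_on]``, transform all of X; returns (X', transform)."""
    fit_on = np.asarray(fit_on)
    if len(fit_on) == 0:
        raise ValueError("empty training set")
    mu = X[fit_on].mean(axis=0)
    sd = X[fit_on].std(axis=0)
    guard = sd < 1e-12
    sd = np.where(guard, 1.0, sd)
    mu = np.where(guard, 0.0, mu)
    fp = hashlib.sha1(np.sort(fit_on).astype(np.int64).tobytes()).hexdigest()[:16]
    tf = Standardizer(mean=mu, std=sd, fit_fingerprint=fp)
    return tf.transform(X), tf


DEFAULT_PENALTIES = (0.1, 1.0, 10.0, 100.0)


def svm_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    penalties=DEFAULT_PENALTIES,
    gammas=None,
    seed: int = 0,
):
    """RBF-SVM with validation-set grid search over (penalty, gamma).

    Default gammas scale with feature dimension d: {0.1/d, 1/d, 10/d}.
    Ties are broken toward the smallest penalty, then the smallest gamma;
    the winning model is refit on the training rows alone.
    Returns (model, best_params, grid_accuracies).
    """
    if len(set(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    d = X_train.shape[1]
    if gammas is None:
        gammas = (0.1 / d, 1.0 / d, 10.0 / d)
    best = None
    grid = {}
    for C in sorted(penalties):
        for g in sorted(gammas):
            model = SVC(C=C, gamma=g, kernel="rbf", random_state=seed)
            model.fit(X_train, y_train)
            acc = float(np.mean(model.predict(X_val) == y_val))
            grid[(C, g)] = acc
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, g)
    _, C, g = best
    model = SVC(C=C, gamma=g, kernel="rbf", random_state=seed)
    model.fit(X_train, y_train)
    return model, {"C": C, "gamma": g, "val_accuracy": best[0]}, grid


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, ordered by class_names
    class_names: list[str]
    per_class_accuracy: dict = field(default_factory=dict)

    def row_normalized(self) -> np.ndarray:
        sums = self.confusion.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.confusion / sums


def evaluate(predictions, labels, class_names: list[str]) -> EvalReport:
    """Accuracy plus the confusion matrix (rows = true class)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    unknown = set(labels) - set(class_names)
    if unknown:
        raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")
    conf = _sk_confusion(labels, predictions, labels=class_names)
    acc = float(np.mean(predictions == labels))
    per_class = {}
    for i, name in enumerate(class_names):
        n = conf[i].sum()
        per_class[name] = float(conf[i, i] / n) if n else float("nan")
    return EvalReport(
        accuracy=acc, confusion=conf, class_names=list(class_names), per_class_accuracy=per_class
    )


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean accuracy over repeats plus the pooled confusion matrix."""
    if not reports:
        raise ValueError("no reports to aggregate")
    names = reports[0].class_names
    pooled = sum(r.confusion for r in reports)
    accs = [r.accuracy for r in reports]
    per_class = {}
    for i, name in enumerate(names):
        n = pooled[i].sum()
        per_class[name] = float(pooled[i, i] / n) if n else float("nan")
    return {
        "per_repeat_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "per_class_accuracy": per_class,
        "confusion": pooled,
        "class_names": names,
    }
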