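"""Classical classifiers and evaluation protocols.

Two classifiers operate on the handcrafted or codebook representations:

* a linear one-vs-rest max-margin classifier (hinge-loss SVM); the
  misclassification penalty C is chosen by stratified 10-fold
  cross-validated accuracy over a small grid.  The linear solver is
  scikit-learn's liblinear binding; the one-vs-rest argmax decision rule
  and the C selection live here.
* a random forest: an ensemble of decision trees predicting by majority
  vote, deterministic given its seed.

Evaluation supports a stratified 80/20 holdout and leave-one-subject-out
(LOSO) cross-validation.  The split unit is the *recording*: every window
or descriptor derived from one recording travels to the same side of the
split, because 50%-overlapped windows from one recording are
near-duplicates and splitting them across sides would leak.  A
window-level split (``unit="window"``) exists for completeness.  Any
subject (LOSO) or recording (holdout) with items on both sides of a split
is a hard error, never a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


class LeakageError(RuntimeError):
    """A split unit appears on both sides of a train/test split."""


@dataclass
class LabeledDataset:
    """Feature matrix with labels, subjects and split-unit group ids."""

    X: np.ndarray
    y: np.ndarray                       # class label per row
    subjects: np.ndarray                # subject id per row
    groups: np.ndarray                  # recording id per row (split unit)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        self.groups = np.asarray(self.groups)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subjects) == len(self.groups) == n):
            raise ValueError("X, y, subjects, groups must align")
        if np.isnan(self.X).any():
            raise ValueError("NaN in feature matrix")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


@dataclass
class SplitSpec:
    """How to split: stratified holdout or leave-one-subject-out."""

    strategy: str = "holdout"           # "holdout" | "loso"
    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True
    unit: str = "recording"             # "recording" | "window"

    def __post_init__(self) -> None:
        if self.strategy not in ("holdout", "loso"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    """Predictions and confusion counts for one evaluated split."""

    accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray               # (n_classes, n_classes) counts
    classes: list[str]
    n_train: int
    n_test: int
    split: SplitSpec | None = None
    predictions: np.ndarray | None = None
    fold: str | None = None             # subject held out (loso)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "fold": self.fold,
        }


def make_report(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray,
                n_train: int, split: SplitSpec | None = None,
                fold: str | None = None) -> EvalReport:
    classes = np.asarray(classes)
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    per_class = {}
    for c in classes:
        row = conf[idx[c]]
        per_class[str(c)] = float(row[idx[c]] / row.sum()) if row.sum() else float("nan")
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else float("nan")
    return EvalReport(
        accuracy=acc,
        per_class_accuracy=per_class,
        confusion=conf,
        classes=[str(c) for c in classes],
        n_train=n_train,
        n_test=len(y_true),
        split=split,
        predictions=np.asarray(y_pred),
        fold=fold,
    )


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------

def _svm_estimator(C: float, standardize: bool, seed: int):
    svm = LinearSVC(C=C, multi_class="ovr", random_state=seed, max_iter=20000)
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", svm)])
    return svm


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    *,
    standardize: bool = True,
):
    """Fit a linear one-vs-rest SVM with C chosen by cross-validation.

    One binary hinge-loss model per class; prediction is the argmax of the
    per-class decision scores.  C is picked by mean stratified
    ``cv_folds``-fold accuracy over ``C_grid``; if the rarest class has
    fewer members than ``cv_folds`` the fold count drops to that size with
    a warning, so every fold sees every class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    min_class = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (rarest class size)",
                       cv_folds, folds)
    if folds >= 2 and len(C_grid) > 1:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        mean_acc = []
        for C in C_grid:
            accs = []
            for tr, va in skf.split(X, y):
                est = _svm_estimator(C, standardize, seed)
                est.fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[va]) == y[va]))
            mean_acc.append(np.mean(accs))
        best_C = C_grid[int(np.argmax(mean_acc))]
        logger.info("selected C=%g (CV accuracies %s)", best_C,
                    dict(zip(C_grid, np.round(mean_acc, 4))))
    else:
        best_C = C_grid[0]
    est = _svm_estimator(best_C, standardize, seed)
    est.fit(X, y)
    est.selected_C_ = best_C
    return est


def train_random_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 0
):
    """Fit a majority-vote random forest (sqrt feature sampling)."""
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    rf.fit(np.asarray(X, dtype=float), np.asarray(y))
    return rf


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def check_no_leakage(units: np.ndarray, train_idx: np.ndarray,
                     test_idx: np.ndarray, what: str = "recording") -> None:
    """Raise :class:`LeakageError` if any unit sits on both sides."""
    both = set(units[train_idx]) & set(units[test_idx])
    if both:
        raise LeakageError(
            f"{what}(s) on both sides of the split: {sorted(both)[:5]}"
        )


def holdout_split(
    dataset: LabeledDataset, split: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (train, test) for a stratified holdout split.

    With ``unit="recording"`` the split is drawn over distinct group ids,
    stratified by class so every class appears on both sides where counts
    allow; all rows of a group land together.
    """
    rng = np.random.default_rng(split.seed)
    if split.unit == "window":
        n = len(dataset.y)
        perm = rng.permutation(n)
        n_train = int(round(split.train_fraction * n))
        return perm[:n_train], perm[n_train:]
    groups, first = np.unique(dataset.groups, return_index=True)
    group_label = dataset.y[first]
    train_groups: list = []
    test_groups: list = []
    if split.stratified:
        for c in np.unique(group_label):
            g = groups[group_label == c]
            g = g[rng.permutation(len(g))]
            n_train = int(round(split.train_fraction * len(g)))
            n_train = min(max(n_train, 1), len(g) - 1) if len(g) > 1 else n_train
            train_groups.extend(g[:n_train])
            test_groups.extend(g[n_train:])
    else:
        g = groups[rng.permutation(len(groups))]
        n_train = int(round(split.train_fraction * len(g)))
        train_groups, test_groups = list(g[:n_train]), list(g[n_train:])
    train_idx = np.flatnonzero(np.isin(dataset.groups, train_groups))
    test_idx = np.flatnonzero(np.isin(dataset.groups, test_groups))
    check_no_leakage(dataset.groups, train_idx, test_idx, "recording")
    return train_idx, test_idx


def loso_folds(dataset: LabeledDataset):
    """Yield (subject, train_idx, test_idx) per held-out subject."""
    subjects = np.unique(dataset.subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    for s in subjects:
        test_idx = np.flatnonzero(dataset.subjects == s)
        train_idx = np.flatnonzero(dataset.subjects != s)
        check_no_leakage(dataset.subjects, train_idx, test_idx, "subject")
        yield str(s), train_idx, test_idx


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def _fit_fresh(model, X, y):
    try:
        est = clone(model)
    except TypeError:                   # not an sklearn estimator: a factory
        est = model(X, y)
        return est
    est.fit(X, y)
    return est


def evaluate(
    model, dataset: LabeledDataset, split: SplitSpec
) -> EvalReport | tuple[list[EvalReport], EvalReport]:
    """Train on the split's training side only, score the held-out side.

    ``model`` is either an unfitted sklearn-style estimator (cloned and
    fitted per fold) or a factory ``f(X_train, y_train) -> fitted model``,
    so every training artifact — including the SVM's internal CV — touches
    only training rows.

    holdout -> one :class:`EvalReport`; loso -> (per-subject reports,
    pooled report over all held-out predictions).
    """
    classes = dataset.classes
    if split.strategy == "holdout":
        tr, te = holdout_split(dataset, split)
        est = _fit_fresh(model, dataset.X[tr], dataset.y[tr])
        pred = est.predict(dataset.X[te])
        return make_report(dataset.y[te], pred, classes, len(tr), split)
    reports = []
    all_true, all_pred = [], []
    for subject, tr, te in loso_folds(dataset):
        est = _fit_fresh(model, dataset.X[tr], dataset.y[tr])
        pred = est.predict(dataset.X[te])
        reports.append(
            make_report(dataset.y[te], pred, classes, len(tr), split,
                        fold=subject)
        )
        all_true.append(dataset.y[te])
        all_pred.append(pred)
    pooled = make_report(
        np.concatenate(all_true), np.concatenate(all_pred), classes,
        n_train=len(dataset.y), split=split, fold="pooled",
    )
    return reports, pooled
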