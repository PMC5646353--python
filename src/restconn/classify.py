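"""SVM classification of cognitive state from EEG and clinical features.

Scalar clinical covariates (SUVR, ApoE coding) are classified with a linear
kernel; multivariate EEG feature sets use a polynomial kernel (gamma 0.25,
degree 3).  Validation is ten repeated stratified 75/25 splits; the capacity
constant C is chosen from a logarithmic 1..1000 grid by mean test accuracy
over the splits, and the chosen C is logged.  Three accuracies are reported
per the validation convention: training (on each split's training portion),
testing (held-out 25%), and *overall* -- the split-trained model scored on
the pooled train+test data, which by construction falls between the training
and testing accuracies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import config

log = logging.getLogger("restconn")


@dataclass
class ClassificationReport:
    feature_set: str
    kernel: str
    C: float
    gamma: float
    accuracy_train: float
    accuracy_test: float
    accuracy_overall: float
    folds: int
    seed: int | None
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in (self.accuracy_train, self.accuracy_test, self.accuracy_overall):
            if not 0.0 <= a <= 100.0:
                raise ValueError("accuracies are percentages in [0, 100]")

    def as_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "accuracy_train": self.accuracy_train,
            "accuracy_test": self.accuracy_test,
            "accuracy_overall": self.accuracy_overall,
            "folds": self.folds,
            "seed": self.seed,
        }


def svm_classify(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "poly",
    feature_set: str = "eeg",
    seed: int | None = None,
    n_splits: int = 10,
    test_size: float = 0.25,
    c_grid: tuple[float, ...] = config.SVM_C_GRID,
    gamma: float = config.SVM_GAMMA,
    degree: int = config.SVM_POLY_DEGREE,
    feature_names: list[str] | None = None,
) -> ClassificationReport:
    """Classify two groups with repeated stratified 75/25 validation.

    ``features`` is subjects x measures (standardized internally); constant
    features are dropped with a warning.  Returns percentage accuracies.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("classification needs two classes")
    if counts.min() < 8:
        raise ValueError("need at least 8 subjects per class")
    if kernel not in ("linear", "poly"):
        raise ValueError(f"unsupported kernel {kernel!r}")

    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    keep = np.ptp(X, axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left")

    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=seed
    )
    splits = list(splitter.split(X, y))

    def run(C: float) -> tuple[float, float, float]:
        acc_tr, acc_te, acc_all = [], [], []
        for tr, te in splits:
            clf = make_pipeline(
                StandardScaler(),
                SVC(kernel=kernel, C=C, gamma=gamma, degree=degree),
            )
            clf.fit(X[tr], y[tr])
            acc_tr.append(clf.score(X[tr], y[tr]))
            acc_te.append(clf.score(X[te], y[te]))
            acc_all.append(clf.score(X, y))
        return float(np.mean(acc_tr)), float(np.mean(acc_te)), float(np.mean(acc_all))

    results = {C: run(C) for C in c_grid}
    best_C = max(results, key=lambda C: results[C][1])
    tr, te, overall = results[best_C]
    log.info("svm: feature_set=%s kernel=%s selected C=%g", feature_set, kernel, best_C)
    return ClassificationReport(
        feature_set=feature_set,
        kernel=kernel,
        C=best_C,
        gamma=gamma if kernel == "poly" else 0.0,
        accuracy_train=100.0 * tr,
        accuracy_test=100.0 * te,
        accuracy_overall=100.0 * overall,
        folds=n_splits,
        seed=seed,
        dropped_features=dropped,
    )
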