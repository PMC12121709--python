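"""Single-trial direction decoding with bootstrap splits and shuffled-label nulls.

A linear maximum-margin classifier (SVM, hinge loss, C = 1) is trained
on repeated random 10:90 test:train splits balanced across the two
motion directions.  Each bootstrap split also yields a matched null
accuracy from a classifier trained on shuffled training labels (test
labels intact), giving an empirical chance distribution per analysis.
Features are standardized using training-fold statistics only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .preprocess import TrialMatrix

logger = logging.getLogger(__name__)

DEFAULT_TEST_FRACTION = 0.10
DEFAULT_N_BOOT = 5000


@dataclass
class AccuracyResult:
    """Bootstrap decoding accuracies with a matched shuffled-label null."""

    accuracies: np.ndarray
    null_accuracies: np.ndarray
    n_boot: int
    test_fraction: float
    seed: int | None = None
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        for arr in (self.accuracies, self.null_accuracies):
            a = np.asarray(arr, float)
            if a.size != self.n_boot:
                raise ValueError("accuracy array length must equal n_boot")
            if ((a < 0) | (a > 1)).any():
                raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null_accuracies))

    def percentile_interval(self, level: float = 95.0) -> tuple[float, float]:
        lo = (100.0 - level) / 2.0
        q = np.percentile(self.accuracies, [lo, 100.0 - lo])
        return float(q[0]), float(q[1])

    def null_interval(self, level: float = 95.0) -> tuple[float, float]:
        lo = (100.0 - level) / 2.0
        q = np.percentile(self.null_accuracies, [lo, 100.0 - lo])
        return float(q[0]), float(q[1])

    def above_null(self, percentile: float = 95.0) -> bool:
        """Is the mean accuracy above the given percentile of the null?"""
        return self.mean_accuracy > float(np.percentile(self.null_accuracies, percentile))

    def summary(self) -> dict:
        lo, hi = self.percentile_interval()
        nlo, nhi = self.null_interval()
        return {
            "mean_accuracy": self.mean_accuracy,
            "accuracy_ci95": [lo, hi],
            "null_mean": self.mean_null,
            "null_ci95": [nlo, nhi],
            "n_boot": self.n_boot,
            "test_fraction": self.test_fraction,
            **self.meta,
        }


def balanced_split(
    labels: np.ndarray,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split with a test set balanced across classes.

    The test set receives ``max(1, round(test_fraction * min class
    count))`` trials per class; the remaining trials form the training
    set.  In the degenerate one-trial-per-class case a balanced test set
    would empty the training set, so one trial goes to each set instead
    (minimum rule, logged).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to split")
    min_count = int(counts.min())
    k = max(1, int(round(test_fraction * min_count)))
    if k >= min_count:
        if min_count == 1:
            logger.info("one trial per class: assigning one trial per set (minimum rule)")
            order = rng.permutation(classes.size)
            test = np.array([rng.choice(np.flatnonzero(labels == classes[order[0]]))])
            train = np.setdiff1d(np.arange(labels.size), test)
            return train, test
        k = min_count - 1
    test_parts = []
    for c in classes:
        ids = np.flatnonzero(labels == c)
        test_parts.append(rng.choice(ids, size=k, replace=False))
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


def _fit_score(x_train, y_train, x_test, y_test, C: float, kernel: str) -> float:
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    clf = SVC(C=C, kernel=kernel)
    clf.fit((x_train - mu) / sd, y_train)
    pred = clf.predict((x_test - mu) / sd)
    return float(np.mean(pred == y_test))


def decode_direction(
    matrix: TrialMatrix,
    condition=None,
    rotated: bool | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    C: float = 1.0,
    kernel: str = "linear",
    min_trials: int = 20,
) -> AccuracyResult:
    """Decode toward/away from trial amplitudes for one condition filter.

    Returns ``n_boot`` bootstrap test accuracies and ``n_boot`` matched
    shuffled-training-label null accuracies computed on the same splits.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sub = matrix.select(condition=condition, rotated=rotated)
    if sub.n_trials < min_trials:
        raise ValueError(
            f"only {sub.n_trials} trials after filtering (need >= {min_trials})")
    features = np.asarray(sub.data, float)
    if not np.isfinite(features).all():
        raise ValueError("non-finite features")
    y = np.where(sub.labels["direction"].to_numpy() == "toward", 1, -1)
    return decode_features(
        features, y, n_boot=n_boot, seed=seed, test_fraction=test_fraction,
        C=C, kernel=kernel,
        meta={"condition": condition, "rotated": rotated},
    )


def decode_features(
    features: np.ndarray,
    labels: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    C: float = 1.0,
    kernel: str = "linear",
    meta: dict | None = None,
) -> AccuracyResult:
    """Bootstrap-decode an arbitrary (trials x features) array (core loop)."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    acc = np.empty(n_boot)
    null = np.empty(n_boot)
    for b in range(n_boot):
        # independent child streams per bootstrap keep results reproducible
        # regardless of how many draws each split consumes
        child = np.random.default_rng(rng.integers(0, 2**31))
        train, test = balanced_split(labels, test_fraction, rng=child)
        acc[b] = _fit_score(features[train], labels[train],
                            features[test], labels[test], C, kernel)
        shuffled = child.permutation(labels[train])
        null[b] = _fit_score(features[train], shuffled,
                             features[test], labels[test], C, kernel)
    return AccuracyResult(acc, null, n_boot=n_boot, test_fraction=test_fraction,
                          seed=seed, meta=meta or {})


def perspective_average(left: AccuracyResult, right: AccuracyResult) -> AccuracyResult:
    """Average the two monocular perspective-cue results, element-wise."""
    if left.n_boot != right.n_boot:
        raise ValueError("mismatched n_boot")
    meta = {"condition": "perspective", "averaged_from":
            [left.meta.get("condition"), right.meta.get("condition")]}
    return AccuracyResult(
        (np.asarray(left.accuracies) + np.asarray(right.accuracies)) / 2.0,
        (np.asarray(left.null_accuracies) + np.asarray(right.null_accuracies)) / 2.0,
        n_boot=left.n_boot, test_fraction=left.test_fraction,
        seed=left.seed, meta=meta,
    )
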