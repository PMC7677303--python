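"""Incremental Feature Selection over an mRMR ranking with LOOCV SVM.

For r = 1..max_r the top-r ranked sites form the feature set of an RBF-kernel
SVM (cost 1, gamma = 1/p, one-vs-one multiclass voting — the defaults of the
classical svm() implementation) whose accuracy is estimated by leave-one-out
cross-validation: each sample is predicted by a model trained on all other
samples.  The curve of (r, accuracy) pairs locates the smallest subset with
maximal accuracy — the signature.

Feature standardization is on by default and, unlike implementations that
scale the pooled data before splitting, uses training-fold statistics only,
so the held-out sample never leaks into the scaler.  The pooled variant is
available via ``standardize="pooled"`` for compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .io import BetaMatrix, ClassLabels
from .mrmr import MRMRRanking


@dataclass(frozen=True)
class ClassifierConfig:
    """Maximum-margin classifier settings mirroring e1071-style defaults.

    gamma accepts the sentinel "1/p" (kernel width 1 / number of features)
    or a positive number; ``standardize`` is True (fold-safe), False, or
    "pooled" (scale on all samples before splitting — leaks, kept only for
    compatibility with implementations that scale up front).
    """

    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | str = "1/p"
    standardize: bool | str = True
    multiclass_scheme: str = "one_vs_one_vote"

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the rbf kernel is supported")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if isinstance(self.gamma, str):
            if self.gamma != "1/p":
                raise ValueError("gamma must be a positive number or '1/p'")
        elif self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.standardize not in (True, False, "pooled"):
            raise ValueError("standardize must be True, False or 'pooled'")
        if self.multiclass_scheme != "one_vs_one_vote":
            raise ValueError("only one-vs-one voting is supported")


@dataclass(frozen=True)
class IFSCurve:
    """LOOCV accuracy of nested top-r subsets, r = 1..max_r in order."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        for k, (r, acc) in enumerate(self.points, start=1):
            if r != k:
                raise ValueError("curve r values must be exactly 1..max_r in order")
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy out of [0, 1] at r={r}: {acc}")

    @property
    def max_r(self) -> int:
        return len(self.points)

    def accuracies(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


def _scale(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.ones(train.shape[1])
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through centred
    return (train - mean) / sd, (test - mean) / sd


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ClassifierConfig,
) -> np.ndarray:
    classes = np.unique(y_train)
    if classes.size == 1:
        # degenerate fold: the held-out sample's class vanished from training
        return np.repeat(classes[0], X_test.shape[0])
    gamma = "auto" if config.gamma == "1/p" else float(config.gamma)
    clf = SVC(C=config.cost, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def loocv_predict(
    matrix: BetaMatrix, labels: ClassLabels, config: ClassifierConfig | None = None
) -> list[str]:
    """Leave-one-out predicted class per sample, in matrix column order.

    Each sample is predicted by a classifier trained on all other samples;
    when standardization is fold-safe the scaler statistics come from the
    training fold alone.  Deterministic given inputs and config.
    """
    config = config or ClassifierConfig()
    if matrix.n_sites == 0:
        raise ValueError("feature subset is empty")
    if matrix.n_samples < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    X = matrix.values.T  # samples x features
    y = np.array(labels.for_samples(matrix.sample_ids))

    if config.standardize == "pooled":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd

    n = X.shape[0]
    predictions: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train, y_train = X[mask], y[mask]
        X_test = X[i : i + 1]
        if config.standardize is True:
            X_train, X_test = _scale(X_train, X_test)
        predictions.append(str(_fit_predict(X_train, y_train, X_test, config)[0]))
    return predictions


def loocv_accuracy(
    matrix: BetaMatrix, labels: ClassLabels, config: ClassifierConfig | None = None
) -> float:
    """Fraction of samples whose LOOCV prediction matches the true class."""
    predicted = loocv_predict(matrix, labels, config)
    truth = labels.for_samples(matrix.sample_ids)
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def ifs_curve(
    matrix: BetaMatrix,
    labels: ClassLabels,
    ranking: MRMRRanking,
    max_r: int,
    config: ClassifierConfig | None = None,
) -> IFSCurve:
    """LOOCV accuracy of every nested top-r prefix of the ranking."""
    if max_r < 1:
        raise ValueError("max_r must be >= 1")
    if max_r > len(ranking):
        raise ValueError(f"max_r={max_r} exceeds ranking length {len(ranking)}")
    points = []
    for r in range(1, max_r + 1):
        subset = matrix.restrict(list(ranking.probe_ids[:r]))
        points.append((r, loocv_accuracy(subset, labels, config)))
    return IFSCurve(points=tuple(points))


def select_signature_size(curve: IFSCurve) -> int:
    """Smallest subset size attaining the curve's maximal accuracy."""
    if not curve.points:
        raise ValueError("curve is empty")
    accs = curve.accuracies()
    return int(np.argmax(accs)) + 1  # argmax returns the first maximum
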