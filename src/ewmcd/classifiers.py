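"""Incremental classifier adapters for the prequential harness.

The harness consumes any object satisfying :class:`ClassifierAdapter`:
``learn(X, y)`` updates the model from a labeled batch (which may
contain a single class) and ``predict(X)`` returns binary labels without
mutating state.

:class:`NearestCentroidAdapter` is the built-in reference classifier — a
minimal incremental learner with no dependencies beyond numpy, kept
deliberately simple so the oversampling effect is easy to reason about:
it maintains a running mean per class over everything it has been
trained on, so the *number* of positive training instances directly
controls how fast the positive centroid tracks a moved class.  Adapters
over scikit-learn's ``partial_fit`` estimators are provided for
comparison with established incremental models.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "ClassifierAdapter",
    "NearestCentroidAdapter",
    "GaussianNBAdapter",
    "SGDAdapter",
    "MajorityClassAdapter",
    "make_classifier",
]


@runtime_checkable
class ClassifierAdapter(Protocol):
    """Behavioral contract for incremental binary classifiers."""

    def learn(self, X: np.ndarray, y: np.ndarray) -> None:
        """Update the model from a labeled batch (may be single-class)."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary labels (1 = positive); must not mutate state."""


class NearestCentroidAdapter:
    """Incremental nearest-centroid classifier (running class means).

    Predicts the class whose centroid is nearest in Euclidean distance.
    Until a class has been observed, its centroid is undefined and the
    other class is predicted (all-negative before any training).
    """

    def __init__(self) -> None:
        self._sums: dict[int, np.ndarray] = {}
        self._counts: dict[int, int] = {}

    def learn(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        for label in np.unique(y):
            rows = X[y == label]
            if int(label) not in self._sums:
                self._sums[int(label)] = rows.sum(axis=0)
                self._counts[int(label)] = rows.shape[0]
            else:
                self._sums[int(label)] += rows.sum(axis=0)
                self._counts[int(label)] += rows.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if not self._counts:
            return np.zeros(n, dtype=int)
        if 1 not in self._counts:
            return np.zeros(n, dtype=int)
        if 0 not in self._counts:
            return np.ones(n, dtype=int)
        c0 = self._sums[0] / self._counts[0]
        c1 = self._sums[1] / self._counts[1]
        d0 = ((X - c0) ** 2).sum(axis=1)
        d1 = ((X - c1) ** 2).sum(axis=1)
        return (d1 <= d0).astype(int)

    def centroid(self, label: int) -> np.ndarray | None:
        if label not in self._counts:
            return None
        return self._sums[label] / self._counts[label]


class _PartialFitAdapter:
    """Wrap a scikit-learn estimator exposing ``partial_fit``."""

    classes = np.array([0, 1])

    def __init__(self, estimator) -> None:
        self._est = estimator
        self._fitted = False

    def learn(self, X: np.ndarray, y: np.ndarray) -> None:
        self._est.partial_fit(
            np.asarray(X, dtype=float),
            np.asarray(y, dtype=int),
            classes=self.classes,
        )
        self._fitted = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            return np.zeros(np.asarray(X).shape[0], dtype=int)
        return np.asarray(self._est.predict(np.asarray(X, dtype=float)), dtype=int)


class GaussianNBAdapter(_PartialFitAdapter):
    """Incremental Gaussian naive Bayes (scikit-learn ``partial_fit``)."""

    def __init__(self) -> None:
        super().__init__(GaussianNB())


class SGDAdapter(_PartialFitAdapter):
    """Incremental linear model trained by SGD (log loss)."""

    def __init__(self, seed: int = 0) -> None:
        super().__init__(SGDClassifier(loss="log_loss", random_state=seed))


class MajorityClassAdapter:
    """Predicts the most frequent training label; a sanity baseline."""

    def __init__(self) -> None:
        self._counts = np.zeros(2, dtype=int)

    def learn(self, X: np.ndarray, y: np.ndarray) -> None:
        y = np.asarray(y, dtype=int)
        self._counts += np.bincount(y, minlength=2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        label = int(np.argmax(self._counts))
        return np.full(np.asarray(X).shape[0], label, dtype=int)


_REGISTRY = {
    "nearest-centroid": NearestCentroidAdapter,
    "gaussian-nb": GaussianNBAdapter,
    "sgd": SGDAdapter,
    "majority": MajorityClassAdapter,
}


def make_classifier(name: str, seed: int = 0) -> ClassifierAdapter:
    """Instantiate a registered adapter by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    if cls is SGDAdapter:
        return cls(seed=seed)
    return cls()
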