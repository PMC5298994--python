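"""K-nearest-neighbor classification on descriptor subsets, with the
leave-one-out score used as the genetic algorithm's fitness.

The classifier is deliberately small and fully deterministic:

* Euclidean distance over the selected descriptor columns (the matrix is
  assumed pre-scaled by the caller; see :func:`poreperm.prep.standardize`);
* distance ties broken toward the lower molecule index (the stable order of
  the matrix);
* vote ties (possible for even k) broken toward the non-permeant class,
  the conservative call for a permeability assay, configurable via
  ``tie_label``.

With two classes and the panel sizes involved here (9-16 molecules) k=1 is
the default; larger k degenerates quickly at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import DescriptorMatrix, NON_PERMEANT

__all__ = ["LooResult", "SubsetKNNClassifier", "knn_classify", "loo_fitness"]


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out tally: each molecule predicted from the other n-1."""

    n_correct: int
    n_total: int
    per_molecule: tuple[tuple[str, str, str], ...]  # (name, true, predicted)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "per_molecule": [list(row) for row in self.per_molecule],
        }


def _vote(labels: Sequence[str], tie_label: str) -> str:
    """Majority vote; ties go to ``tie_label`` if among the tied classes,
    else to the lexicographically smallest tied class (deterministic)."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    winners = sorted(lab for lab, c in counts.items() if c == top)
    if len(winners) == 1:
        return winners[0]
    return tie_label if tie_label in winners else winners[0]


class SubsetKNNClassifier(BaseEstimator, ClassifierMixin):
    """KNN classifier restricted to a binary descriptor subset.

    Parameters
    ----------
    k : int, default=1
        Number of neighbors.
    subset : array-like of bool/0-1 or None, default=None
        Mask over feature columns; None selects every column.
    tie_label : str, default="non_permeant"
        Class awarded on vote ties.

    Notes
    -----
    Distances are Euclidean over the selected columns of the data exactly as
    given — no internal scaling.  Distance ties are broken toward the lower
    training-row index, so predictions are invariant to nothing but the
    stored row order, and fully reproducible.
    """

    def __init__(self, k: int = 1, subset=None, tie_label: str = NON_PERMEANT):
        self.k = k
        self.subset = subset
        self.tie_label = tie_label

    def _mask(self, n_features: int) -> np.ndarray:
        if self.subset is None:
            return np.ones(n_features, dtype=bool)
        mask = np.asarray(self.subset).astype(bool)
        if mask.shape != (n_features,):
            raise ValueError(
                f"subset length {mask.size} does not match {n_features} features"
            )
        return mask

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds {X.shape[0]} training molecules")
        mask = self._mask(X.shape[1])
        if not mask.any():
            raise ValueError("empty descriptor subset")
        self.X_ = X
        self.y_ = y
        self.mask_ = mask
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        train = self.X_[:, self.mask_]
        out = []
        for q in X:
            d = np.linalg.norm(train - q[self.mask_], axis=1)
            # stable sort: equal distances keep ascending row index
            order = np.argsort(d, kind="stable")[: self.k]
            out.append(_vote([self.y_[i] for i in order], self.tie_label))
        return np.asarray(out)


def knn_classify(
    train_matrix: DescriptorMatrix,
    query: Sequence[float],
    k: int = 1,
    subset=None,
    tie_label: str = NON_PERMEANT,
) -> str:
    """Classify one query vector (full descriptor length) against a labelled
    training matrix, using only the descriptors selected by ``subset``."""
    if train_matrix.labels is None:
        raise ValueError("training matrix must be labelled")
    clf = SubsetKNNClassifier(k=k, subset=subset, tie_label=tie_label)
    clf.fit(train_matrix.values, train_matrix.labels.to_numpy())
    return str(clf.predict(np.asarray(query, dtype=float))[0])


def loo_fitness(
    matrix: DescriptorMatrix,
    subset=None,
    k: int = 1,
    tie_label: str = NON_PERMEANT,
) -> LooResult:
    """Leave-one-out KNN score on a labelled matrix.

    Each molecule is predicted from the remaining n-1; ``n_correct`` is the
    GA fitness.  An all-zero subset scores 0 by convention (no distance is
    defined), with every prediction recorded as ``"(undefined)"``.
    """
    if matrix.labels is None:
        raise ValueError("loo_fitness requires class labels")
    n = matrix.n_molecules
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 molecules")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} training molecules per fold")
    X = matrix.values
    y = matrix.labels.to_numpy()
    names = matrix.molecule_names
    mask = (
        np.ones(X.shape[1], dtype=bool)
        if subset is None
        else np.asarray(subset).astype(bool)
    )
    if mask.shape != (X.shape[1],):
        raise ValueError("subset length does not match descriptor count")
    if not mask.any():
        per = tuple((names[i], str(y[i]), "(undefined)") for i in range(n))
        return LooResult(n_correct=0, n_total=n, per_molecule=per)
    Xs = X[:, mask]
    # full pairwise distances once; each fold masks out its own row
    diff = Xs[:, None, :] - Xs[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    per = []
    n_correct = 0
    for i in range(n):
        d = np.delete(dist[i], i)
        rest = np.delete(np.arange(n), i)
        order = np.argsort(d, kind="stable")[:k]
        pred = _vote([y[rest[j]] for j in order], tie_label)
        ok = pred == y[i]
        n_correct += int(ok)
        per.append((names[i], str(y[i]), str(pred)))
    return LooResult(n_correct=n_correct, n_total=n, per_molecule=tuple(per))
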