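"""Descriptor-matrix preprocessing.

Three standard steps precede the GA/KNN subset search:

1. :func:`filter_noninformative` removes descriptor columns that carry no
   usable signal for a small molecule panel — columns missing for more than
   one molecule, and columns equal to zero for all molecules but exactly one.
   A column missing for a *single* molecule is kept and that one cell is
   imputed with the column mean, so downstream distances stay well defined.
2. :func:`standardize` z-scores each column (sample statistics, ddof=1).
   Descriptor scales in the packaged table span roughly 0.5 to 1,800, so raw
   Euclidean distance would be dominated by the largest-scale columns;
   standardization is therefore the default upstream of KNN.
3. :func:`assign_categories` annotates the physicochemical category of each
   of the eleven selected descriptors (electronegativity, ionization
   potential, polarizability, size and geometry, topological flexibility,
   valence); anything else is ``uncategorized``.

:func:`separation_report` summarises, per descriptor, the value ranges of
the permeant and non-permeant classes and whether those ranges are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import DescriptorMatrix, NON_PERMEANT, PERMEANT

__all__ = [
    "FilterReport",
    "SeparationRecord",
    "CATEGORY_MAP",
    "filter_noninformative",
    "standardize",
    "assign_categories",
    "separation_report",
    "NonInformativeFilter",
]

logger = logging.getLogger(__name__)

#: Physicochemical category of each selected descriptor.
CATEGORY_MAP: Mapping[str, str] = {
    "TDB6e": "electronegativity",
    "ATSC5s": "electronegativity",
    "GATS5s": "electronegativity",
    "TDB8i": "ionization_potential",
    "TDB10i": "ionization_potential",
    "TDB6p": "polarizability",
    "TDB6r": "size_and_geometry",
    "TDB6v": "size_and_geometry",
    "TDB5u": "size_and_geometry",
    "RotBtFrac": "topological_flexibility",
    "VP-6": "valence",
}

UNCATEGORIZED = "uncategorized"


@dataclass(frozen=True)
class FilterReport:
    """Outcome of :func:`filter_noninformative`.

    The three name lists are disjoint and their union is the input
    descriptor set.
    """

    kept: tuple[str, ...]
    dropped_missing: tuple[str, ...]
    dropped_degenerate_zero: tuple[str, ...]
    imputed: tuple[tuple[str, str], ...] = ()  # (descriptor, molecule) pairs

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "dropped_missing": list(self.dropped_missing),
            "dropped_degenerate_zero": list(self.dropped_degenerate_zero),
            "imputed": [list(pair) for pair in self.imputed],
        }


def filter_noninformative(
    matrix: DescriptorMatrix,
) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop descriptors that are missing-heavy or all-but-one zero.

    A descriptor is dropped if it is missing for more than one molecule, or
    if it equals 0 (exact equality on parsed values) for every molecule
    except exactly one.  A descriptor missing for exactly one molecule is
    kept; the missing cell is imputed with the mean of the present values
    and logged.

    Raises
    ------
    ValueError
        If the matrix has fewer than two molecules or every descriptor is
        dropped.
    """
    if matrix.n_molecules < 2:
        raise ValueError("need at least 2 molecules to assess descriptors")
    data = matrix.data
    kept: list[str] = []
    dropped_missing: list[str] = []
    dropped_zero: list[str] = []
    imputed: list[tuple[str, str]] = []
    out = {}
    n = matrix.n_molecules
    for name in data.columns:
        col = data[name]
        n_missing = int(col.isna().sum())
        if n_missing > 1:
            dropped_missing.append(name)
            continue
        present = col.dropna()
        if (present == 0.0).sum() == n - 1 and len(present) == n:
            dropped_zero.append(name)
            continue
        if n_missing == 1:
            molecule = col.index[col.isna()][0]
            fill = float(present.mean())
            col = col.fillna(fill)
            imputed.append((name, molecule))
            logger.info(
                "descriptor %r: imputed missing value for %r with column mean %.6g",
                name, molecule, fill,
            )
        kept.append(name)
        out[name] = col
    if not kept:
        raise ValueError("all descriptors were dropped as non-informative")
    filtered = DescriptorMatrix(pd.DataFrame(out, index=data.index), matrix.labels)
    report = FilterReport(
        kept=tuple(kept),
        dropped_missing=tuple(dropped_missing),
        dropped_degenerate_zero=tuple(dropped_zero),
        imputed=tuple(imputed),
    )
    return filtered, report


def standardize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Z-score each descriptor column to mean 0, sample sd 1 (ddof=1).

    Constant columns cannot be scaled and map to all zeros with a logged
    warning.  Requires at least two molecules and no missing values.
    """
    if matrix.n_molecules < 2:
        raise ValueError("standardization needs at least 2 molecules")
    if matrix.has_missing():
        raise ValueError("standardization requires a complete matrix")
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [n for n, c in zip(matrix.descriptor_names, constant) if c]
        logger.warning("constant descriptor columns set to zero: %s", names)
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (values - mean) / safe_sd
    scaled[:, constant] = 0.0
    return DescriptorMatrix(
        pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns),
        matrix.labels,
    )


def assign_categories(names: Iterable[str]) -> dict[str, str]:
    """Map descriptor names to their physicochemical category."""
    return {name: CATEGORY_MAP.get(name, UNCATEGORIZED) for name in names}


@dataclass(frozen=True)
class SeparationRecord:
    """Class-range summary for one descriptor.

    ``separates`` is True iff the permeant and non-permeant value ranges are
    disjoint; ``direction`` then records which class sits higher
    (``"permeant_higher"`` / ``"permeant_lower"``), else ``None``.
    """

    descriptor: str
    min_permeant: float
    max_permeant: float
    min_nonpermeant: float
    max_nonpermeant: float
    separates: bool
    direction: str | None

    def to_dict(self) -> dict:
        return asdict(self)


def separation_report(matrix: DescriptorMatrix) -> dict[str, SeparationRecord]:
    """Per-descriptor class ranges and disjointness on a labelled matrix.

    Raises
    ------
    ValueError
        If labels are absent or only one class is present.
    """
    if matrix.labels is None:
        raise ValueError("separation_report requires class labels")
    labels = matrix.labels
    perm_mask = (labels == PERMEANT).to_numpy()
    nonp_mask = (labels == NON_PERMEANT).to_numpy()
    if not perm_mask.any() or not nonp_mask.any():
        raise ValueError("both permeant and non-permeant molecules are required")
    report: dict[str, SeparationRecord] = {}
    for name in matrix.descriptor_names:
        col = matrix.data[name].to_numpy()
        p, q = col[perm_mask], col[nonp_mask]
        min_p, max_p = float(np.nanmin(p)), float(np.nanmax(p))
        min_n, max_n = float(np.nanmin(q)), float(np.nanmax(q))
        if min_p > max_n:
            separates, direction = True, "permeant_higher"
        elif max_p < min_n:
            separates, direction = True, "permeant_lower"
        else:
            separates, direction = False, None
        report[name] = SeparationRecord(
            descriptor=name,
            min_permeant=min_p,
            max_permeant=max_p,
            min_nonpermeant=min_n,
            max_nonpermeant=max_n,
            separates=separates,
            direction=direction,
        )
    return report


class NonInformativeFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the non-informative descriptor filter.

    Operates on 2-D arrays or DataFrames; fit learns which columns survive
    (and the imputation value for singly-missing columns), transform applies
    the selection.  Equivalent to :func:`filter_noninformative` on a
    :class:`DescriptorMatrix`.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_features,)
        Mask of kept columns.
    report_ : FilterReport
        Names use column labels when the input is a DataFrame, else
        stringified column indices.
    """

    def fit(self, X, y=None):
        frame = X.data if isinstance(X, DescriptorMatrix) else pd.DataFrame(X)
        frame = frame.astype(float)
        if isinstance(X, DescriptorMatrix):
            labels = X.labels
        else:
            labels = None
        frame.columns = [str(c) for c in frame.columns]
        filtered, report = filter_noninformative(DescriptorMatrix(frame, labels))
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        self.support_ = np.asarray([c in set(report.kept) for c in frame.columns])
        self.fill_values_ = filtered.data.mean(axis=0).to_dict()
        self.report_ = report
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        frame = X.data if isinstance(X, DescriptorMatrix) else pd.DataFrame(X)
        frame = frame.astype(float)
        frame.columns = [str(c) for c in frame.columns]
        kept = [c for c, keep in zip(self.feature_names_in_, self.support_) if keep]
        out = frame[kept].copy()
        for col in kept:
            if out[col].isna().any():
                out[col] = out[col].fillna(self.fill_values_[col])
        if isinstance(X, DescriptorMatrix):
            return DescriptorMatrix(out, X.labels)
        return out.to_numpy()

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_
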