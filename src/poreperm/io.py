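"""Packaged reference tables and descriptor-matrix CSV input/output.

The package ships two small reference tables from the Cx39 hemichannel
permeability study as plain-CSV package data:

* a 16-dye uptake panel (name, molecular weight, net charge, permeability
  class, whether uptake was inhibited by a hemichannel blocker), and
* a 9-molecule x 11-descriptor matrix of the molecular descriptors that
  jointly separate permeant from non-permeant dyes.

User-supplied descriptor tables (PaDEL-style CSV: one name column followed
by numeric descriptor columns) are read and written through
:func:`read_descriptor_csv` / :func:`write_descriptor_csv`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DyeRecord",
    "DyePanel",
    "DescriptorMatrix",
    "FixtureIntegrityError",
    "DescriptorFormatError",
    "DEFAULT_MISSING_TOKENS",
    "PERMEANT",
    "NON_PERMEANT",
    "load_dye_panel",
    "load_descriptor_table",
    "read_descriptor_csv",
    "write_descriptor_csv",
]

PERMEANT = "permeant"
NON_PERMEANT = "non_permeant"

#: Missing-value tokens produced by common descriptor software.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "Infinity", "-Infinity")

# sha256 of the packaged CSVs; load_* verifies these so silent corruption of
# package data is caught at load time rather than downstream.
_FIXTURE_SHA256 = {
    "dye_panel.csv": "009c19735239916d67b2a3a21b2c74d81964cab6f96165425a8e38aa2faf0709",
    "descriptor_table.csv": "e916bade5fb72c399638283b2d2c9758ed684503b423905da115db8deab902fd",
}

# The descriptor table prints two molecule names slightly differently from the
# dye panel; labels are joined through this explicit alias map (descriptor
# table name -> panel name).  Names are otherwise matched exactly.
_PANEL_ALIASES = {
    "Ethidium homodimer-2": "Ethidium homodimer",
    "Procion orange MX2R": "Procion Orange MX2R",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture data failed its checksum or shape invariant."""


class DescriptorFormatError(ValueError):
    """A descriptor CSV violates the expected table layout."""


@dataclass(frozen=True)
class DyeRecord:
    """One fluorescent tracer from the uptake panel.

    Parameters
    ----------
    name : str
        Commercial dye name.
    molecular_weight : float
        Molecular weight in Da; must be positive.
    net_charge : int
        Net charge in elementary charges, within [-4, +4] for this panel.
    uptake_class : str
        ``"permeant"`` if the dye enters cells through open hemichannels,
        ``"non_permeant"`` otherwise.
    blocker_inhibited : str
        ``"yes"`` if uptake was abolished by a hemichannel blocker;
        ``"not_applicable"`` for non-permeant dyes.
    """

    name: str
    molecular_weight: float
    net_charge: int
    uptake_class: str
    blocker_inhibited: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be positive: {self.name}")
        if not -4 <= self.net_charge <= 4:
            raise ValueError(f"net_charge out of range [-4, 4]: {self.name}")
        if self.uptake_class not in (PERMEANT, NON_PERMEANT):
            raise ValueError(f"unknown uptake_class {self.uptake_class!r}")
        if self.uptake_class == NON_PERMEANT and self.blocker_inhibited != "not_applicable":
            raise ValueError(
                f"non-permeant dye {self.name!r} must have blocker_inhibited='not_applicable'"
            )


@dataclass(frozen=True)
class DyePanel:
    """Ordered collection of :class:`DyeRecord` with unique names."""

    records: tuple[DyeRecord, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("dye names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> DyeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def count(self, uptake_class: str) -> int:
        return sum(r.uptake_class == uptake_class for r in self.records)

    def labels(self) -> pd.Series:
        """Per-dye permeability class, indexed by dye name."""
        return pd.Series(
            {r.name: r.uptake_class for r in self.records}, name="uptake_class"
        )


class DescriptorMatrix:
    """A molecules x descriptors table with optional per-molecule class labels.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = molecules,
    columns = descriptors, ``NaN`` = missing) that enforces unique names on
    both axes and keeps labels aligned with the molecule index.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        labels: pd.Series | Sequence[str] | dict[str, str] | None = None,
    ) -> None:
        if data.index.has_duplicates:
            raise ValueError("molecule names must be unique")
        if data.columns.has_duplicates:
            raise ValueError("descriptor names must be unique")
        self.data = data.astype(float)
        if labels is None:
            self.labels: pd.Series | None = None
        else:
            if isinstance(labels, dict):
                labels = pd.Series(labels)
            if isinstance(labels, pd.Series):
                labels = labels.reindex(data.index)
                if labels.isna().any():
                    missing = list(labels.index[labels.isna()])
                    raise ValueError(f"labels missing for molecules: {missing}")
            else:
                if len(labels) != len(data.index):
                    raise ValueError("labels length must match molecule count")
                labels = pd.Series(list(labels), index=data.index)
            self.labels = labels.rename("label")

    # -- basic accessors ---------------------------------------------------
    @property
    def molecule_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_molecules(self) -> int:
        return self.data.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    def value(self, molecule: str, descriptor: str) -> float:
        return float(self.data.at[molecule, descriptor])

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def select(self, descriptors: Iterable[str]) -> "DescriptorMatrix":
        """New matrix restricted to the given descriptor columns (order kept)."""
        cols = list(descriptors)
        unknown = [c for c in cols if c not in self.data.columns]
        if unknown:
            raise KeyError(f"unknown descriptors: {unknown}")
        return DescriptorMatrix(self.data[cols].copy(), self.labels)

    def copy(self) -> "DescriptorMatrix":
        return DescriptorMatrix(
            self.data.copy(), None if self.labels is None else self.labels.copy()
        )

    def equals(self, other: "DescriptorMatrix") -> bool:
        same_data = self.data.equals(other.data)
        if self.labels is None or other.labels is None:
            return same_data and (self.labels is None) == (other.labels is None)
        return same_data and self.labels.equals(other.labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = "labelled" if self.labels is not None else "unlabelled"
        return (
            f"DescriptorMatrix({self.n_molecules} molecules x "
            f"{self.n_descriptors} descriptors, {lab})"
        )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(filename: str) -> Path:
    path = resources.files("poreperm.data").joinpath(filename)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[filename]:
        raise FixtureIntegrityError(
            f"checksum mismatch for packaged fixture {filename}: {digest}"
        )
    return Path(str(path))


def load_dye_panel() -> DyePanel:
    """Load the packaged 16-dye uptake panel.

    Returns
    -------
    DyePanel
        16 records: 10 permeant dyes and 6 non-permeant dyes, in the
        published order.
    """
    df = pd.read_csv(_fixture_path("dye_panel.csv"))
    records = tuple(
        DyeRecord(
            name=row["name"],
            molecular_weight=float(row["molecular_weight"]),
            net_charge=int(row["net_charge"]),
            uptake_class=row["uptake_class"],
            blocker_inhibited=row["blocker_inhibited"],
        )
        for _, row in df.iterrows()
    )
    panel = DyePanel(records)
    if len(panel) != 16 or panel.count(PERMEANT) != 10 or panel.count(NON_PERMEANT) != 6:
        raise FixtureIntegrityError("dye panel fixture has unexpected composition")
    return panel


def load_descriptor_table() -> DescriptorMatrix:
    """Load the packaged 9x11 descriptor matrix with permeability labels.

    Labels are joined from the dye panel (6 permeant, 3 non-permeant
    molecules); the matrix has no missing values.
    """
    matrix = read_descriptor_csv(_fixture_path("descriptor_table.csv"))
    if matrix.data.shape != (9, 11):
        raise FixtureIntegrityError("descriptor table fixture is not 9x11")
    if matrix.has_missing():
        raise FixtureIntegrityError("descriptor table fixture has missing values")
    panel_labels = load_dye_panel().labels()
    labels = {
        name: panel_labels[_PANEL_ALIASES.get(name, name)]
        for name in matrix.molecule_names
    }
    return DescriptorMatrix(matrix.data, labels)


# ---------------------------------------------------------------------------
# Descriptor CSV I/O
# ---------------------------------------------------------------------------

def read_descriptor_csv(
    path: str | Path,
    name_column: str = "Name",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> DescriptorMatrix:
    """Read a PaDEL-style descriptor CSV.

    The first column (or ``name_column``) holds molecule names; every other
    column is a numeric descriptor.  Cells equal to one of ``missing_tokens``
    (or otherwise non-numeric) become missing values.

    Raises
    ------
    DescriptorFormatError
        If the name column is absent, names are duplicated, or there are no
        descriptor columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if name_column not in df.columns:
        raise DescriptorFormatError(f"name column {name_column!r} not found in {path}")
    names = df[name_column]
    if names.duplicated().any():
        dupes = sorted(names[names.duplicated()].unique())
        raise DescriptorFormatError(f"duplicate molecule names: {dupes}")
    body = df.drop(columns=[name_column])
    if body.shape[1] == 0:
        raise DescriptorFormatError("no descriptor columns found")
    token_set = set(missing_tokens)

    def _parse(cell: str) -> float:
        # python's float() is correctly rounded; pd.to_numeric's fast parser
        # can be off by an ulp, breaking bit-exact round trips
        if cell.strip() in token_set:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            return np.nan

    numeric = body.map(_parse).astype(float)
    numeric.index = pd.Index(names, name="molecule")
    return DescriptorMatrix(numeric)


def write_descriptor_csv(
    matrix: DescriptorMatrix, path: str | Path, name_column: str = "Name"
) -> Path:
    """Write a matrix as a descriptor CSV re-readable by :func:`read_descriptor_csv`.

    Values are written with 17 significant digits (shortest exact decimal
    for a double) so a round trip preserves them bit-for-bit; missing
    values are written as ``NA``.
    """
    if matrix.n_molecules == 0:
        raise DescriptorFormatError("refusing to write a matrix with no molecules")
    out = matrix.data.copy()
    out.index.name = name_column
    path = Path(path)
    out.to_csv(path, float_format="%.17g", na_rep="NA")
    return path
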