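"""Core tabular containers and CSV ingestion.

The whole pipeline trades in :class:`FeatureTable` objects: a rectangular
matrix of named, non-negative clinical measurements plus one integer class
label per row.  Class codes follow a fixed four-way convention:

====  ============
code  meaning
====  ============
1     normal
2     type 1 diabetes
3     type 2 diabetes
4     gestational diabetes
====  ============

Source files with other label conventions (e.g. the Pima Indian Diabetes
binary outcome column) are mapped through an explicit :class:`Schema`;
labels are never guessed from the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParameterError, SchemaError

__all__ = [
    "CLASS_NAMES",
    "VALID_LABELS",
    "FeatureTable",
    "Schema",
    "PID_COLUMNS",
    "pid_schema",
    "load_table",
    "save_model",
    "load_model",
]

CLASS_NAMES: dict[int, str] = {1: "normal", 2: "type1", 3: "type2", 4: "gestational"}
VALID_LABELS = frozenset(CLASS_NAMES)

#: canonical column set of the Pima Indian Diabetes dialect
PID_COLUMNS = (
    "pregnancies",
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
    "pedigree",
    "age",
)

MISSING_POLICIES = ("keep", "drop-row", "impute-column-median")


@dataclass
class FeatureTable:
    """Rows = patients, columns = named numeric attributes, plus labels."""

    attribute_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D matrix")
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise InputError("duplicate attribute names")
        if self.values.shape[1] != len(self.attribute_names):
            raise InputError(
                f"{len(self.attribute_names)} attribute names for "
                f"{self.values.shape[1]} value columns"
            )
        if self.labels.shape != (self.values.shape[0],):
            raise InputError("labels must align with value rows")
        if self.values.shape[0] < 1:
            raise InputError("table must contain at least one row")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise InputError(f"labels outside {{1,2,3,4}}: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.attribute_names.index(name)
        except ValueError:
            raise InputError(f"unknown attribute {name!r}") from None
        return self.values[:, j]

    def take_rows(self, idx: np.ndarray) -> "FeatureTable":
        return dataclasses.replace(
            self, values=self.values[idx], labels=self.labels[idx]
        )

    def select_attributes(self, names: list[str]) -> "FeatureTable":
        cols = [self.attribute_names.index(n) for n in names]
        return dataclasses.replace(
            self, attribute_names=list(names), values=self.values[:, cols]
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.attribute_names)
        df[label_column] = self.labels
        return df

    def to_csv(self, path: str | Path, label_column: str = "label") -> None:
        self.to_dataframe(label_column).to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        provenance: str = "",
    ) -> "FeatureTable":
        if label_column not in df.columns:
            raise SchemaError(f"label column {label_column!r} not present")
        names = [c for c in df.columns if c != label_column]
        return cls(
            attribute_names=names,
            values=df[names].to_numpy(dtype=float),
            labels=df[label_column].to_numpy(),
            provenance=provenance,
        )


@dataclass
class Schema:
    """Maps source CSV columns onto canonical attributes and class codes.

    ``column_map`` renames source columns to canonical attribute names,
    ``label_column`` names the source outcome column and ``label_encoding``
    maps its raw values to the package's class codes.
    """

    column_map: dict[str, str]
    label_column: str
    label_encoding: dict[int | str, int] = field(
        default_factory=lambda: {1: 1, 2: 2, 3: 3, 4: 4}
    )

    def __post_init__(self) -> None:
        canon = list(self.column_map.values())
        if len(set(canon)) != len(canon):
            raise SchemaError("a canonical attribute is mapped more than once")
        if self.label_column in canon:
            raise SchemaError("label column collides with an attribute name")
        for code in self.label_encoding.values():
            if code not in VALID_LABELS:
                raise SchemaError(f"encoded label {code} outside {{1,2,3,4}}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            column_map=dict(raw["column_map"]),
            label_column=raw["label_column"],
            label_encoding=dict(raw.get("label_encoding", {1: 1, 2: 2, 3: 3, 4: 4})),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "column_map": self.column_map,
                    "label_column": self.label_column,
                    "label_encoding": self.label_encoding,
                },
                fh,
            )


def pid_schema() -> Schema:
    """Schema for the Pima Indian Diabetes layout.

    Binary outcome 0 (no diabetes) maps to class 1 and outcome 1 to class 2,
    the type-1 convention of the reference pipeline.
    """
    return Schema(
        column_map={c: c for c in PID_COLUMNS},
        label_column="outcome",
        label_encoding={0: 1, 1: 2},
    )


def load_table(
    path: str | Path,
    schema: Schema,
    missing: str = "keep",
) -> FeatureTable:
    """Read a delimited text file into a :class:`FeatureTable`.

    Parameters
    ----------
    path
        CSV file with a header row, comma separated, UTF-8.
    schema
        Column mapping and label encoding.
    missing
        Policy for unparseable numeric cells: ``"keep"`` retains them as NaN,
        ``"drop-row"`` removes the affected rows, ``"impute-column-median"``
        fills with the column median of the parseable values.
    """
    if missing not in MISSING_POLICIES:
        raise ParameterError(
            f"unknown missing-value policy {missing!r}; "
            f"choose one of {MISSING_POLICIES}"
        )
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise InputError(f"{path}: file contains no data rows")
    for col in list(schema.column_map) + [schema.label_column]:
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} missing")

    canonical = list(schema.column_map.values())
    values = (
        df[list(schema.column_map)]
        .rename(columns=schema.column_map)[canonical]
        .apply(pd.to_numeric, errors="coerce")
    )
    if missing == "drop-row":
        keep = ~values.isna().any(axis=1)
        values, df = values[keep], df[keep]
        if values.shape[0] == 0:
            raise InputError(f"{path}: no rows left after dropping missing values")
    elif missing == "impute-column-median":
        values = values.fillna(values.median())

    labels = np.empty(values.shape[0], dtype=int)
    raw_labels = df[schema.label_column].tolist()
    for i, raw in enumerate(raw_labels):
        if raw in schema.label_encoding:
            labels[i] = schema.label_encoding[raw]
        elif isinstance(raw, (int, np.integer, float)) and int(raw) == raw and int(
            raw
        ) in schema.label_encoding:
            labels[i] = schema.label_encoding[int(raw)]
        else:
            raise InputError(
                f"{path}: row {i}: label value {raw!r} not in schema encoding"
            )
    return FeatureTable(
        attribute_names=canonical,
        values=values.to_numpy(dtype=float),
        labels=labels,
        provenance=str(path),
    )


def save_model(model, path: str | Path) -> None:
    """Serialize a trained cascade to a versioned JSON archive."""
    from .cascade import save_model as _save

    _save(model, path)


def load_model(path: str | Path):
    """Load a cascade saved by :func:`save_model`."""
    from .cascade import load_model as _load

    return _load(path)
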