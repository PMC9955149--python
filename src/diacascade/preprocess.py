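"""Normalization, four-level discretization and the random train/test split.

Normalization divides every column by its maximum, mapping non-negative
clinical measurements onto [0, 1].  Discretization then bins the normalized
values at the fixed interior cut points 0.25 / 0.5 / 0.75 into levels 1-4.
The bins are half-open and left-closed, with the top bin closed at 1:

    [0, 0.25) -> 1    [0.25, 0.5) -> 2    [0.5, 0.75) -> 3    [0.75, 1] -> 4

which partitions [0, 1] exactly while preserving the stated cut points.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .data_model import FeatureTable
from .errors import InputError, ParameterError

__all__ = [
    "BIN_EDGES",
    "DiscretizedTable",
    "SplitResult",
    "normalize",
    "column_maxima",
    "normalize_with",
    "discretize",
    "split",
]

#: interior cut points on the normalized [0, 1] scale (read-only)
BIN_EDGES: tuple[float, float, float] = (0.25, 0.5, 0.75)


@dataclass
class DiscretizedTable:
    """A feature table whose values have been mapped to levels 1-4."""

    attribute_names: list[str]
    levels: np.ndarray
    labels: np.ndarray
    bin_edges: tuple[float, float, float] = BIN_EDGES
    provenance: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.levels, (1, 2, 3, 4)).all():
            raise InputError("discretized levels must lie in {1,2,3,4}")
        if list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise InputError("bin edges must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return self.levels.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.levels.shape[1]

    def select_attributes(self, names: list[str]) -> "DiscretizedTable":
        cols = [self.attribute_names.index(n) for n in names]
        return dataclasses.replace(
            self, attribute_names=list(names), levels=self.levels[:, cols]
        )

    def as_feature_table(self) -> FeatureTable:
        """View the integer levels as a numeric feature table."""
        return FeatureTable(
            attribute_names=list(self.attribute_names),
            values=self.levels.astype(float),
            labels=self.labels,
            provenance=self.provenance,
        )


@dataclass
class SplitResult:
    train: FeatureTable | DiscretizedTable
    test: FeatureTable | DiscretizedTable
    seed: int
    fraction: float


def column_maxima(table: FeatureTable) -> np.ndarray:
    """Per-column maxima used as normalization divisors.

    Raises on all-zero or negative columns, for which division by the
    maximum is undefined or leaves the [0, 1] range.
    """
    vals = table.values
    if np.isnan(vals).any():
        raise InputError("table contains missing values; resolve them first")
    if (vals < 0).any():
        j = int(np.argwhere((vals < 0).any(axis=0))[0][0])
        raise InputError(
            f"column {table.attribute_names[j]!r} contains negative values; "
            "max-normalization assumes non-negative measurements"
        )
    maxima = vals.max(axis=0)
    if (maxima == 0).any():
        j = int(np.argmax(maxima == 0))
        raise InputError(
            f"column {table.attribute_names[j]!r} is all zero; "
            "cannot divide by its maximum"
        )
    return maxima


def normalize(table: FeatureTable) -> FeatureTable:
    """Divide each column by its own maximum (range becomes [0, 1])."""
    maxima = column_maxima(table)
    return dataclasses.replace(table, values=table.values / maxima)


def normalize_with(table: FeatureTable, maxima: np.ndarray) -> FeatureTable:
    """Normalize with divisors learned elsewhere (leakage-safe mode).

    Values exceeding the stored maxima are clipped to 1 so the result stays
    a valid input for :func:`discretize`.
    """
    maxima = np.asarray(maxima, dtype=float)
    if maxima.shape != (table.n_attributes,):
        raise ParameterError("maxima length must match attribute count")
    return dataclasses.replace(
        table, values=np.clip(table.values / maxima, 0.0, 1.0)
    )


def discretize(table: FeatureTable) -> DiscretizedTable:
    """Map normalized values to levels 1-4 at the fixed cut points."""
    vals = table.values
    if np.isnan(vals).any():
        raise InputError("table contains missing values; resolve them first")
    if (vals < 0).any() or (vals > 1).any():
        raise InputError(
            "values outside [0, 1]; normalize the table before discretizing"
        )
    levels = np.digitize(vals, BIN_EDGES) + 1
    return DiscretizedTable(
        attribute_names=list(table.attribute_names),
        levels=levels,
        labels=table.labels,
        bin_edges=BIN_EDGES,
        provenance=table.provenance,
    )


def _train_size(n: int, fraction: float) -> int:
    # round-half-up on fraction * n
    return int(math.floor(fraction * n + 0.5))


def split(
    table: FeatureTable | DiscretizedTable,
    fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> SplitResult:
    """Random row partition into train and test.

    ``|train| = floor(fraction * n + 0.5)`` (round-half-up).  With
    ``stratify=True`` the same rounding is applied within each class so
    small minority classes cannot vanish from either side.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    n = table.n_rows
    if n < 2:
        raise InputError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for c in np.unique(table.labels):
            rows = np.flatnonzero(table.labels == c)
            perm = rng.permutation(rows)
            k = _train_size(len(rows), fraction)
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
        tr = np.sort(np.concatenate(train_idx))
        te = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        k = _train_size(n, fraction)
        tr, te = np.sort(perm[:k]), np.sort(perm[k:])

    def _take(t, idx):
        if isinstance(t, DiscretizedTable):
            return dataclasses.replace(t, levels=t.levels[idx], labels=t.labels[idx])
        return t.take_rows(idx)

    return SplitResult(
        train=_take(table, tr), test=_take(table, te), seed=seed, fraction=fraction
    )
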