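"""Attribute selection by discretized co-occurrence strength.

For each attribute the 4 discrete levels are crossed with the 4 class codes
to give a 16-row ratio matrix: cell (level v, class c) is the number of rows
where the attribute takes level v *and* the class is c, divided by the
number of rows where the attribute takes level v and the class is *not* c.
A level that occurs almost exclusively within one class therefore produces
a large ratio.  The attribute's strength is the maximum cell of its column,
and the weakest attributes are discarded.

Raw ratios are undefined whenever a (level, class) co-occurrence is
class-pure, so both the ratio matrix and the per-class attribute weight add
a smoothing constant ``s`` to numerator and denominator (``s = 1`` by
default); ``s = 0`` restores the raw ratios with +inf cells allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .preprocess import DiscretizedTable

__all__ = [
    "N_LEVELS",
    "N_CLASSES",
    "StrengthReport",
    "AttributeWeight",
    "strength_matrix",
    "select_attributes",
    "attribute_weight",
]

# level grid and class count are fixed by the discretization and the
# four-way diagnosis coding; they are constants, not configuration
N_LEVELS = 4
N_CLASSES = 4


@dataclass
class StrengthReport:
    """Per-(level, class) co-occurrence ratios and derived attribute ranking.

    ``ratio_matrix`` has 16 rows ordered level-major: row index
    ``(level - 1) * 4 + (class - 1)``; columns follow ``attribute_names``.
    """

    attribute_names: list[str]
    ratio_matrix: np.ndarray
    strength: np.ndarray
    ranking: list[str]
    smoothing: float
    discarded: list[str] = field(default_factory=list)

    def row_index(self, level: int, klass: int) -> int:
        if level not in range(1, N_LEVELS + 1) or klass not in range(1, N_CLASSES + 1):
            raise ParameterError("level and class must lie in 1..4")
        return (level - 1) * N_CLASSES + (klass - 1)

    def cell(self, level: int, klass: int, attribute: str) -> float:
        j = self.attribute_names.index(attribute)
        return float(self.ratio_matrix[self.row_index(level, klass), j])


@dataclass
class AttributeWeight:
    """Class-association weight of one attribute: odds that its modal level
    within the class is present rather than absent among that class's rows."""

    attribute: str
    klass: int
    modal_level: int
    weight: float


def strength_matrix(disc: DiscretizedTable, smoothing: float = 1.0) -> StrengthReport:
    """Compute the 16 x K ratio matrix and per-attribute strengths.

    With ``smoothing == 0`` cells with a zero denominator are +inf when the
    numerator is positive and 0 when it is also zero; +inf sorts highest.
    """
    if disc.n_rows < 1:
        raise InputError("empty table")
    if smoothing < 0:
        raise ParameterError("smoothing must be >= 0")

    levels, labels = disc.levels, disc.labels
    k = disc.n_attributes
    ratio = np.empty((N_LEVELS * N_CLASSES, k))
    for v in range(1, N_LEVELS + 1):
        at_level = levels == v  # (n, k) mask
        for c in range(1, N_CLASSES + 1):
            in_class = labels == c
            num = (at_level & in_class[:, None]).sum(axis=0).astype(float)
            den = (at_level & ~in_class[:, None]).sum(axis=0).astype(float)
            row = (v - 1) * N_CLASSES + (c - 1)
            if smoothing > 0:
                ratio[row] = (num + smoothing) / (den + smoothing)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    cells = num / den
                cells[(den == 0) & (num > 0)] = np.inf
                cells[(den == 0) & (num == 0)] = 0.0
                ratio[row] = cells

    strength = ratio.max(axis=0)
    order = sorted(range(k), key=lambda j: (-strength[j], j))
    ranking = [disc.attribute_names[j] for j in order]
    return StrengthReport(
        attribute_names=list(disc.attribute_names),
        ratio_matrix=ratio,
        strength=strength,
        ranking=ranking,
        smoothing=smoothing,
    )


def select_attributes(report: StrengthReport, discard_count: int = 2) -> list[str]:
    """Drop the ``discard_count`` attributes with lowest strength.

    Ties are broken by original column order: the earlier column is kept.
    The kept list preserves the original attribute order.  The report's
    ``discarded`` field is filled in place.
    """
    k = len(report.attribute_names)
    if not 0 <= discard_count < k:
        raise ParameterError(
            f"discard_count must lie in [0, {k}), got {discard_count}"
        )
    # ascending strength; equal strengths discard the later column first
    order = sorted(range(k), key=lambda j: (report.strength[j], -j))
    drop = set(order[:discard_count])
    kept = [n for j, n in enumerate(report.attribute_names) if j not in drop]
    report.discarded = [
        n for j, n in enumerate(report.attribute_names) if j in drop
    ]
    return kept


def attribute_weight(
    disc: DiscretizedTable,
    attribute: str,
    klass: int,
    smoothing: float = 1.0,
) -> AttributeWeight:
    """Presence/absence odds of the attribute's modal level within a class.

    Among the rows of class ``klass``, find the attribute's most frequent
    level (ties resolved to the lowest level) with count ``k`` out of ``m``
    class rows; the weight is ``(k + s) / (m - k + s)``.  An empty class
    with ``s > 0`` yields the pure-prior weight 1.
    """
    if attribute not in disc.attribute_names:
        raise ParameterError(f"unknown attribute {attribute!r}")
    if klass not in range(1, N_CLASSES + 1):
        raise ParameterError(f"class must lie in 1..4, got {klass}")
    if smoothing < 0:
        raise ParameterError("smoothing must be >= 0")

    j = disc.attribute_names.index(attribute)
    col = disc.levels[disc.labels == klass, j]
    m = col.size
    if m == 0:
        counts = np.zeros(N_LEVELS, dtype=int)
    else:
        counts = np.bincount(col, minlength=N_LEVELS + 1)[1:]
    modal = int(np.argmax(counts)) + 1  # argmax takes the lowest level on ties
    k_count = int(counts[modal - 1])
    num, den = k_count + smoothing, (m - k_count) + smoothing
    if den == 0:
        raise InputError(
            "weight undefined: class rows all at the modal level with smoothing 0"
        )
    return AttributeWeight(
        attribute=attribute, klass=klass, modal_level=modal, weight=num / den
    )
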