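"""Evolutionary-stability categorization of orthologous polyQ regions.

Each alignment column inside a region span is classified by the proportion
of sequences carrying a glutamine there:

* **conserved** — >= 80% of rows have Q;
* **unstable** — 20% <= fraction < 80%; the sub-value records whether the
  non-Q remainder is dominated by gaps (**inserted**, i.e. length
  variation), by other residues (**mutated**, i.e. point substitution), or
  tied (**undefined**);
* **uncategorized** — < 20% of rows have Q.

The region then receives one of five categories by majority over its
columns (strict inequalities; uncategorized columns count toward neither
side):

1. **stable** — more conserved than unstable columns;
2. **inserted** — more unstable than conserved, insertions dominating;
3. **mutated** — more unstable than conserved, substitutions dominating;
4. **undefined** — more unstable than conserved but neither 2 nor 3;
5. **uncategorized** — anything else (including ties).

Categories 4 and 5 carry no interpretable stability mechanism and are
excluded from downstream analyses by default.

Gapped rows count in the column denominator: a gap is "not having a
glutamine", and the inserted sub-value explicitly treats gaps as evidence
of length variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Sequence

from .polyq_detect import (
    DEFAULT_MIN_Q,
    DEFAULT_WINDOW,
    OrthologousPolyQRegion,
    extract_orthologous_regions,
)
from .seq_io import GAP, ColumnMap, OrthologAlignment, build_column_map

CONSERVED_THRESHOLD = 0.8
UNCATEGORIZED_THRESHOLD = 0.2


class ColumnValue(str, Enum):
    CONSERVED = "conserved"
    UNSTABLE = "unstable"
    UNCATEGORIZED = "uncategorized"


class ColumnSubvalue(str, Enum):
    INSERTED = "inserted"
    MUTATED = "mutated"
    UNDEFINED = "undefined"
    NONE = "none"


class StabilityCategory(IntEnum):
    STABLE = 1
    INSERTED = 2
    MUTATED = 3
    UNDEFINED = 4
    UNCATEGORIZED = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def informative(self) -> bool:
        """Whether the category carries an interpretable stability mechanism."""
        return self in (
            StabilityCategory.STABLE,
            StabilityCategory.INSERTED,
            StabilityCategory.MUTATED,
        )


@dataclass(frozen=True)
class ColumnClass:
    """Glutamine-conservation classification of one alignment column."""

    col: int  # 1-based column index
    n_rows: int
    n_q: int
    n_gap: int
    n_other: int
    value: ColumnValue
    subvalue: ColumnSubvalue

    @property
    def q_fraction(self) -> float:
        return self.n_q / self.n_rows


@dataclass(frozen=True)
class RegionCategorization:
    """One orthologous region with its per-column classes and category."""

    region: OrthologousPolyQRegion
    columns: tuple[ColumnClass, ...]
    category: StabilityCategory

    def count(self, value: ColumnValue) -> int:
        return sum(1 for c in self.columns if c.value == value)

    def subcount(self, sub: ColumnSubvalue) -> int:
        return sum(1 for c in self.columns if c.subvalue == sub)


def classify_column(
    column_residues: str,
    col: int = 1,
    conserved_threshold: float = CONSERVED_THRESHOLD,
    uncategorized_threshold: float = UNCATEGORIZED_THRESHOLD,
) -> ColumnClass:
    """Classify one alignment column from its residue characters.

    ``column_residues`` holds one character per row ('-' for a gap).  The
    thresholds are applied exactly as >= 80% (conserved) and < 20%
    (uncategorized); 'X' counts as a non-glutamine residue.
    """
    n = len(column_residues)
    if n == 0:
        raise ValueError("empty column")
    n_q = column_residues.count("Q")
    n_gap = column_residues.count(GAP)
    n_other = n - n_q - n_gap
    frac = n_q / n
    if frac >= conserved_threshold:
        value, sub = ColumnValue.CONSERVED, ColumnSubvalue.NONE
    elif frac < uncategorized_threshold:
        value, sub = ColumnValue.UNCATEGORIZED, ColumnSubvalue.NONE
    else:
        value = ColumnValue.UNSTABLE
        if n_gap > n_other:
            sub = ColumnSubvalue.INSERTED
        elif n_other > n_gap:
            sub = ColumnSubvalue.MUTATED
        else:
            sub = ColumnSubvalue.UNDEFINED
    return ColumnClass(
        col=col, n_rows=n, n_q=n_q, n_gap=n_gap, n_other=n_other, value=value, subvalue=sub
    )


def categorize_region(column_classes: Sequence[ColumnClass]) -> StabilityCategory:
    """Assign the five-way stability category from per-column classes.

    Strict majorities throughout; columns classified uncategorized
    contribute to neither the conserved nor the unstable tally, so a span
    of only uncategorized columns (or any tie) falls to category 5.
    """
    if not column_classes:
        raise ValueError("categorize_region requires at least one column")
    c = sum(1 for x in column_classes if x.value == ColumnValue.CONSERVED)
    u = sum(1 for x in column_classes if x.value == ColumnValue.UNSTABLE)
    i = sum(1 for x in column_classes if x.subvalue == ColumnSubvalue.INSERTED)
    m = sum(1 for x in column_classes if x.subvalue == ColumnSubvalue.MUTATED)
    d = sum(1 for x in column_classes if x.subvalue == ColumnSubvalue.UNDEFINED)
    if c > u:
        return StabilityCategory.STABLE
    if u > c:
        if i > m and i > d:
            return StabilityCategory.INSERTED
        if m > i and m > d:
            return StabilityCategory.MUTATED
        return StabilityCategory.UNDEFINED
    return StabilityCategory.UNCATEGORIZED


def categorize_alignment(
    alignment: OrthologAlignment,
    column_map: ColumnMap | None = None,
    min_q: int = DEFAULT_MIN_Q,
    window: int = DEFAULT_WINDOW,
    conserved_threshold: float = CONSERVED_THRESHOLD,
    uncategorized_threshold: float = UNCATEGORIZED_THRESHOLD,
) -> list[RegionCategorization]:
    """Detect, classify and categorize every orthologous polyQ region.

    Classification runs over the merged orthologous column span (the union
    across members).  All five categories are returned; callers decide
    whether to drop the uninformative ones (4 and 5).
    """
    cmap = column_map or build_column_map(alignment)
    out: list[RegionCategorization] = []
    for region in extract_orthologous_regions(alignment, cmap, min_q=min_q, window=window):
        cols = tuple(
            classify_column(
                alignment.column(col - 1),
                col=col,
                conserved_threshold=conserved_threshold,
                uncategorized_threshold=uncategorized_threshold,
            )
            for col in range(region.col_start, region.col_end + 1)
        )
        out.append(
            RegionCategorization(
                region=region, columns=cols, category=categorize_region(cols)
            )
        )
    return out
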