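"""PolyQ detection with the 4-in-6 density rule and projection into alignments.

A polyglutamine region is any maximal span in which every position is
covered by at least one qualifying window — a window of up to ``window``
consecutive residues containing at least ``min_q`` glutamines — trimmed so
that the span begins and ends with 'Q'.  The default 4/6 threshold is the
most permissive commonly used definition and maximizes the number of
detected regions; impurities (non-Q residues inside a region) are allowed.

Within an ortholog alignment, per-row regions are lifted to alignment
columns, and column spans that overlap across rows are merged (transitive
closure) into a single orthologous polyQ region.  Spans that merely touch
are kept separate so that distinct regions never share a column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seq_io import GAP, ColumnMap, OrthologAlignment, build_column_map

logger = logging.getLogger(__name__)

DEFAULT_MIN_Q = 4
DEFAULT_WINDOW = 6


class DetectorConfigError(ValueError):
    """min_q/window combination that can never fire."""


@dataclass(frozen=True)
class PolyQRegion:
    """A detected polyQ region in one sequence.

    Residue coordinates are 1-based inclusive in the ungapped sequence;
    column coordinates (1-based inclusive, set when detected inside an
    alignment) locate the same span in gapped alignment space.
    """

    row_id: str
    start_res: int
    end_res: int
    sequence: str
    start_col: int | None = None
    end_col: int | None = None

    @property
    def n_q(self) -> int:
        return self.sequence.count("Q")

    @property
    def length(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass(frozen=True)
class OrthologousPolyQRegion:
    """A merged alignment-column span in which >=1 row carries a polyQ."""

    set_id: str
    col_start: int  # 1-based inclusive
    col_end: int
    members: tuple[PolyQRegion, ...]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.row_id for m in self.members)


def scan_polyq(
    residues: str,
    min_q: int = DEFAULT_MIN_Q,
    window: int = DEFAULT_WINDOW,
    row_id: str = "",
) -> list[PolyQRegion]:
    """Detect polyQ regions in an ungapped amino-acid string.

    Every window ``residues[i:i+window]`` (truncated at the end of the
    sequence, so a 4-residue pure tract qualifies on its own) containing
    ``>= min_q`` glutamines marks its positions as covered; maximal covered
    runs are then trimmed to terminal glutamines.  Regions are returned
    left to right and never overlap.
    """
    if min_q > window:
        raise DetectorConfigError(f"min_q={min_q} exceeds window={window}")
    if GAP in residues:
        raise ValueError("scan_polyq expects an ungapped sequence")
    s = residues.upper()
    n = len(s)
    if n == 0:
        return []
    # prefix sums of Q counts: q[j] = #Q in s[:j]
    q = [0] * (n + 1)
    for i, ch in enumerate(s):
        q[i + 1] = q[i] + (ch == "Q")
    covered = [False] * n
    for i in range(n):
        j = min(i + window, n)
        if q[j] - q[i] >= min_q:
            for k in range(i, j):
                covered[k] = True
    regions: list[PolyQRegion] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        a, b = i, j - 1
        while a <= b and s[a] != "Q":
            a += 1
        while b >= a and s[b] != "Q":
            b -= 1
        if a <= b:
            regions.append(
                PolyQRegion(
                    row_id=row_id,
                    start_res=a + 1,
                    end_res=b + 1,
                    sequence=s[a : b + 1],
                )
            )
        i = j
    return regions


def extract_orthologous_regions(
    alignment: OrthologAlignment,
    column_map: ColumnMap | None = None,
    min_q: int = DEFAULT_MIN_Q,
    window: int = DEFAULT_WINDOW,
) -> list[OrthologousPolyQRegion]:
    """Scan every row, lift regions to columns, and merge overlapping spans.

    Merging is the transitive closure of column-span overlap; spans that
    touch without sharing a column remain separate regions, so one
    alignment may contain several orthologous polyQ regions.
    """
    cmap = column_map or build_column_map(alignment)
    projected: list[PolyQRegion] = []
    for row in alignment.rows:
        r2c = cmap.res_to_col[row.id]
        for reg in scan_polyq(row.ungapped(), min_q=min_q, window=window, row_id=row.id):
            projected.append(
                replace(
                    reg,
                    start_col=r2c[reg.start_res - 1] + 1,
                    end_col=r2c[reg.end_res - 1] + 1,
                )
            )
    projected.sort(key=lambda r: (r.start_col, r.end_col))
    merged: list[OrthologousPolyQRegion] = []
    group: list[PolyQRegion] = []
    span_end = -1
    for reg in projected:
        if group and reg.start_col <= span_end:  # shares >=1 column
            group.append(reg)
            span_end = max(span_end, reg.end_col)
        else:
            if group:
                merged.append(_close_group(alignment.set_id, group))
            group = [reg]
            span_end = reg.end_col
    if group:
        merged.append(_close_group(alignment.set_id, group))
    return merged


def _close_group(set_id: str, group: list[PolyQRegion]) -> OrthologousPolyQRegion:
    return OrthologousPolyQRegion(
        set_id=set_id,
        col_start=min(r.start_col for r in group),
        col_end=max(r.end_col for r in group),
        members=tuple(group),
    )


def filter_sets(
    alignments: Iterable[OrthologAlignment], min_rows: int = 5
) -> list[OrthologAlignment]:
    """Drop ortholog sets represented by fewer than ``min_rows`` species."""
    alignments = list(alignments)
    kept = [a for a in alignments if a.n_rows >= min_rows]
    n_dropped = len(alignments) - len(kept)
    if n_dropped:
        logger.info(
            "filter_sets: dropped %d of %d set(s) with < %d rows",
            n_dropped,
            len(alignments),
            min_rows,
        )
    return kept
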