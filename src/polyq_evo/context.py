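"""Sequence and structural context around polyQ regions.

Leucine immediately before a polyQ promotes the alpha-helical conformation
the repeat extends on binding, and proline downstream caps the repeat
against aggregation; both signatures track the region's stability
category.  Profiles are built from one randomly chosen representative per
orthologous region (the representative must itself carry the polyQ), with
relative positions counted in the representative's *ungapped* sequence:
-10..-1 before the first glutamine and +1..+10 after the last.

Secondary structure is consumed, not predicted: windows of the region plus
20 flanking residues on each side are exported for an external predictor,
whose one-character-per-residue strings (H = helical, E = extended,
anything else = other) are aggregated per category over positions -10..+10
to avoid border effects in the predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .polyq_detect import OrthologousPolyQRegion, PolyQRegion
from .seq_io import OrthologAlignment
from .stability import StabilityCategory

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10
DEFAULT_SS_FLANK = 20


@dataclass(frozen=True)
class Representative:
    """One sequence chosen to represent an orthologous polyQ region."""

    set_id: str
    row_id: str
    sequence: str  # full ungapped protein sequence
    start_res: int  # 1-based inclusive polyQ span in `sequence`
    end_res: int
    category: StabilityCategory | None = None

    @property
    def uid(self) -> str:
        return f"{self.set_id}|{self.row_id}|{self.start_res}-{self.end_res}"

    def residue_at_offset(self, offset: int) -> str | None:
        """Residue at position -k/+k relative to the region, or None past a terminus."""
        if offset == 0:
            raise ValueError("offset 0 is inside the region")
        idx = (self.start_res - 1 + offset) if offset < 0 else (self.end_res - 1 + offset)
        if 0 <= idx < len(self.sequence):
            return self.sequence[idx]
        return None


def select_representative(
    region: OrthologousPolyQRegion,
    alignment: OrthologAlignment,
    rng: np.random.Generator,
    category: StabilityCategory | None = None,
) -> Representative:
    """Pick one member row uniformly at random to represent the region.

    Members are by construction rows in which a polyQ was detected, so the
    chosen sequence always carries the repeat.  Deterministic for a given
    generator state.
    """
    member: PolyQRegion = region.members[int(rng.integers(len(region.members)))]
    return Representative(
        set_id=region.set_id,
        row_id=member.row_id,
        sequence=alignment.row(member.row_id).ungapped(),
        start_res=member.start_res,
        end_res=member.end_res,
        category=category,
    )


@dataclass
class ContextProfile:
    """Per-position frequency of one residue around polyQ boundaries.

    ``n_samples[pos]`` counts representatives whose sequence extends to
    that offset (shorter flanks are skipped, never padded), and
    ``counts[pos]`` how many of those carry ``residue`` there.
    """

    residue: str
    positions: tuple[int, ...]
    counts: dict[int, int]
    n_samples: dict[int, int]
    background: float | None = None

    def freq(self, pos: int) -> float:
        n = self.n_samples[pos]
        return self.counts[pos] / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": list(self.positions),
                "count": [self.counts[p] for p in self.positions],
                "n": [self.n_samples[p] for p in self.positions],
                "freq": [self.freq(p) for p in self.positions],
            }
        )


def residue_context_profile(
    representatives: Sequence[Representative],
    residue: str,
    flank: int = DEFAULT_FLANK,
) -> ContextProfile:
    """Fraction of representatives carrying ``residue`` at each offset.

    Offsets run -flank..-1 and +1..+flank relative to the region
    boundaries in the ungapped representative sequence; the region
    interior is excluded.
    """
    if not representatives:
        raise ValueError("residue_context_profile: empty representative set")
    positions = tuple(range(-flank, 0)) + tuple(range(1, flank + 1))
    counts = {p: 0 for p in positions}
    n_samples = {p: 0 for p in positions}
    for rep in representatives:
        for pos in positions:
            ch = rep.residue_at_offset(pos)
            if ch is None:
                continue
            n_samples[pos] += 1
            if ch == residue:
                counts[pos] += 1
    return ContextProfile(
        residue=residue, positions=positions, counts=counts, n_samples=n_samples
    )


def background_frequency(sequence_corpus: Iterable[str], residue: str) -> float:
    """Corpus-wide frequency of ``residue`` (gaps excluded)."""
    hit = total = 0
    for seq in sequence_corpus:
        seq = seq.replace("-", "")
        total += len(seq)
        hit += seq.count(residue)
    if total == 0:
        return float("nan")
    return hit / total


@dataclass(frozen=True)
class StructureWindow:
    """A polyQ region plus up to ``flank`` residues either side.

    ``region_start``/``region_end`` are 0-based indices of the polyQ
    within ``sequence`` (windows at a protein terminus are truncated, so
    the left flank may be shorter than requested).
    """

    uid: str
    sequence: str
    region_start: int
    region_end: int
    category: StabilityCategory | None = None


def extract_structure_windows(
    representatives: Sequence[Representative],
    flank: int = DEFAULT_SS_FLANK,
) -> list[StructureWindow]:
    """Cut the region +/- ``flank`` residues out of each representative."""
    windows = []
    for rep in representatives:
        a = max(0, rep.start_res - 1 - flank)
        b = min(len(rep.sequence), rep.end_res + flank)
        windows.append(
            StructureWindow(
                uid=rep.uid,
                sequence=rep.sequence[a:b],
                region_start=rep.start_res - 1 - a,
                region_end=rep.end_res - 1 - a,
                category=rep.category,
            )
        )
    return windows


def write_windows_fasta(windows: Sequence[StructureWindow], path: str | Path) -> None:
    """Emit windows as FASTA for an external secondary-structure predictor.

    The header keeps the region coordinates within the window so the
    returned one-character-per-residue strings can be re-anchored.
    """
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.uid} region={w.region_start + 1}-{w.region_end + 1}\n")
            fh.write(w.sequence + "\n")


def aggregate_structure(
    windows: Sequence[StructureWindow],
    ss_strings: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Per-position secondary-structure proportions around the region.

    ``ss_strings`` maps window uid -> predictor string (one character per
    window residue; H -> helical, E -> extended, else other).  Windows with
    a length mismatch are skipped with a warning.  Returns a tidy frame
    with columns category, position, helical, extended, other, n; the
    three proportions sum to 1 wherever n >= 1.
    """
    tallies: dict[tuple[str, int], dict[str, int]] = {}
    n_skipped = 0
    for w in windows:
        ss = ss_strings.get(w.uid)
        if ss is None:
            continue
        if len(ss) != len(w.sequence):
            n_skipped += 1
            logger.warning(
                "window %s: structure string length %d != window length %d; skipped",
                w.uid,
                len(ss),
                len(w.sequence),
            )
            continue
        cat = w.category.label if w.category is not None else "all"
        for pos in list(range(-flank, 0)) + list(range(1, flank + 1)):
            idx = (w.region_start + pos) if pos < 0 else (w.region_end + pos)
            if not 0 <= idx < len(ss):
                continue
            ch = ss[idx].upper()
            state = "helical" if ch == "H" else "extended" if ch == "E" else "other"
            key = (cat, pos)
            tallies.setdefault(key, {"helical": 0, "extended": 0, "other": 0})
            tallies[key][state] += 1
    if n_skipped:
        logger.warning("aggregate_structure: skipped %d mismatched window(s)", n_skipped)
    rows = []
    for (cat, pos), t in sorted(tallies.items()):
        n = t["helical"] + t["extended"] + t["other"]
        rows.append(
            {
                "category": cat,
                "position": pos,
                "helical": t["helical"] / n,
                "extended": t["extended"] / n,
                "other": t["other"] / n,
                "n": n,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "position", "helical", "extended", "other", "n"]
    )
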