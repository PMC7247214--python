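"""Sequence input/output and gapped/ungapped coordinate bookkeeping.

Ortholog sets arrive as aligned protein FASTA (one file per set) and,
optionally, unaligned coding sequences keyed by the same identifiers.
Everything downstream reasons either in *alignment columns* (gapped) or
*residue positions* (ungapped); :class:`ColumnMap` maintains the exact
bijection between the two for every row.

Internal coordinates are 0-based half-open; everything user-facing is
reported 1-based inclusive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
#: the 20 standard residues, plus 'X' for unknown
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUE_CHARS = AMINO_ACIDS | {"X", GAP}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
GLUTAMINE_CODONS = frozenset({"CAA", "CAG"})


class SeqIOError(ValueError):
    """Base class for fatal input errors in this module."""


class EmptyInputError(SeqIOError):
    pass


class DuplicateIdError(SeqIOError):
    pass


class RaggedAlignmentError(SeqIOError):
    """Rows of an alignment differ in length."""


class PairingError(SeqIOError):
    """No CDS record could be paired with any alignment row."""


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) protein sequence with an identity label."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        bad = set(self.residues) - VALID_RESIDUE_CHARS
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrthologAlignment:
    """An aligned set of orthologous protein sequences.

    All rows have identical (gapped) length and unique ids.  At least two
    rows are required: column conservation is meaningless for a single
    sequence.
    """

    set_id: str
    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise EmptyInputError(
                f"alignment {self.set_id!r}: need at least 2 rows, got {len(self.rows)}"
            )
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"ragged alignment {self.set_id!r}: row lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise EmptyInputError(f"alignment {self.set_id!r}: zero columns")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"alignment {self.set_id!r}: duplicate ids {dupes}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    @property
    def row_ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, row_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(row_id)

    def column(self, col: int) -> str:
        """Residues of 0-based column ``col``, one character per row."""
        return "".join(r.residues[col] for r in self.rows)


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence split into codons (terminal stop already removed)."""

    id: str
    codons: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class ColumnMap:
    """Per-row bijection between alignment columns and ungapped residue indices.

    ``col_to_res[row_id][col]`` gives the 0-based residue index at 0-based
    column ``col`` (absent when the row has a gap there); ``res_to_col`` is
    the inverse.  Residue indices are strictly increasing with column index.
    """

    col_to_res: dict[str, dict[int, int]] = field(default_factory=dict)
    res_to_col: dict[str, dict[int, int]] = field(default_factory=dict)


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment_fasta(path: str | Path, set_id: str | None = None) -> OrthologAlignment:
    """Read one aligned protein FASTA into an :class:`OrthologAlignment`.

    Residues are uppercased and '.' gaps normalized to '-'.  Files that are
    empty, contain duplicate ids or ragged row lengths raise a named error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    rows = []
    for rec in records:
        species = rec.description.split(maxsplit=1)[1] if " " in rec.description else ""
        rows.append(SequenceRecord(id=rec.id, residues=_normalize(str(rec.seq)), species=species))
    return OrthologAlignment(set_id=set_id or path.stem, rows=rows)


def write_alignment_fasta(alignment: OrthologAlignment, path: str | Path) -> None:
    records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.species)
        for r in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read unaligned nucleotide FASTA and split each record into codons.

    A trailing stop codon is dropped.  Records whose length is not a
    multiple of three are excluded with a logged warning rather than
    aborting the run: one malformed CDS should not invalidate the set.
    """
    path = Path(path)
    out: list[CdsRecord] = []
    n_bad = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) == 0 or len(seq) % 3 != 0:
            n_bad += 1
            logger.warning("CDS %s: length %d not divisible by 3; excluded", rec.id, len(seq))
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        out.append(CdsRecord(id=rec.id, codons=tuple(codons)))
    if n_bad:
        logger.warning("%s: excluded %d malformed CDS record(s)", path, n_bad)
    return out


@dataclass
class CdsPairing:
    """Validated pairing of alignment rows with their coding sequences.

    ``valid`` maps row id -> CdsRecord for rows where the codon count equals
    the ungapped residue count and every glutamine is encoded by CAA/CAG.
    ``excluded`` maps row id -> reason for every row that failed a check.
    Excluded rows are dropped from codon analyses only; they remain part of
    all protein-level analyses.
    """

    valid: dict[str, CdsRecord]
    excluded: dict[str, str]


def pair_cds_with_protein(
    alignment: OrthologAlignment, cds_records: Iterable[CdsRecord]
) -> CdsPairing:
    """Pair alignment rows with CDS records sharing the same id.

    Raises :class:`PairingError` when no id overlaps at all; individual
    rows failing the length or Q-codon contract are flagged and excluded.
    """
    by_id = {c.id: c for c in cds_records}
    valid: dict[str, CdsRecord] = {}
    excluded: dict[str, str] = {}
    n_overlap = 0
    for row in alignment.rows:
        cds = by_id.get(row.id)
        if cds is None:
            excluded[row.id] = "no CDS record"
            continue
        n_overlap += 1
        protein = row.ungapped()
        if len(cds.codons) != len(protein):
            excluded[row.id] = (
                f"length mismatch: {len(cds.codons)} codons vs {len(protein)} residues"
            )
            continue
        mismatch = next(
            (
                i
                for i, aa in enumerate(protein)
                if aa == "Q" and cds.codons[i] not in GLUTAMINE_CODONS
            ),
            None,
        )
        if mismatch is not None:
            excluded[row.id] = (
                f"codon mismatch: Q at residue {mismatch + 1} encoded by {cds.codons[mismatch]}"
            )
            continue
        valid[row.id] = cds
    if n_overlap == 0:
        raise PairingError(
            f"alignment {alignment.set_id!r}: no CDS record matches any row id"
        )
    if excluded:
        logger.info(
            "alignment %s: %d row(s) excluded from codon analyses (%s)",
            alignment.set_id,
            len(excluded),
            "; ".join(f"{k}: {v}" for k, v in excluded.items()),
        )
    return CdsPairing(valid=valid, excluded=excluded)


def build_column_map(alignment: OrthologAlignment) -> ColumnMap:
    """Build the per-row column <-> residue index bijection."""
    cmap = ColumnMap()
    for row in alignment.rows:
        c2r: dict[int, int] = {}
        r2c: dict[int, int] = {}
        res = 0
        for col, ch in enumerate(row.residues):
            if ch != GAP:
                c2r[col] = res
                r2c[res] = col
                res += 1
        cmap.col_to_res[row.id] = c2r
        cmap.res_to_col[row.id] = r2c
    return cmap


def average_identity(alignment: OrthologAlignment) -> float:
    """Mean pairwise percent identity over all unordered row pairs.

    Per pair, the denominator is the number of columns where at least one
    row has a residue (double-gap columns are ignored); a gap aligned to a
    residue counts as a mismatch.  Pairs with no comparable column are
    skipped.
    """
    pct: list[float] = []
    for a, b in itertools.combinations(alignment.rows, 2):
        same = 0
        total = 0
        for x, y in zip(a.residues, b.residues):
            if x == GAP and y == GAP:
                continue
            total += 1
            if x == y:
                same += 1
        if total:
            pct.append(100.0 * same / total)
    if not pct:
        return float("nan")
    return float(sum(pct) / len(pct))
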