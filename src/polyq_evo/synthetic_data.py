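"""Synthetic ortholog sets with planted polyQ ground truth.

Stands in for the real inputs (dozens of proteomes, STRING links,
structure predictions) with generated data whose every property is known:
each emitted alignment carries exactly one polyQ region planted to a
chosen stability category, a paired CDS with a controlled CAG fraction
among glutamine codons, flanks with controlled residue enrichments, and a
links table with category-dependent interactor counts.

Construction happens directly in alignment space, column-wise: a fixed
subset of rows (always including row 0) carries glutamine across the
whole region span, and the remaining rows are entirely gap or entirely
substituted, so the per-column (Q, gap, other) counts — and therefore the
category — are exact by construction and no aligner enters the loop.
Per-row right-flank lengths absorb the row's gap count, making ungapped
protein lengths independent of category (the control needed when
comparing interactor counts).  Context enrichments are planted exactly:
with the stated probability the residue is placed, otherwise the draw
excludes it, so the planted probability is the true per-position
frequency.  No phylogenetic correlation between rows is simulated.

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .polyq_detect import scan_polyq
from .seq_io import (
    CdsRecord,
    GAP,
    OrthologAlignment,
    SequenceRecord,
    write_alignment_fasta,
)
from .stability import CONSERVED_THRESHOLD, UNCATEGORIZED_THRESHOLD

logger = logging.getLogger(__name__)

CATEGORY_LABELS = ("stable", "inserted", "mutated", "undefined", "uncategorized")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NON_Q = _AA20.replace("Q", "")

# aa -> tuple of codons, from the standard nuclear code
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, ())
    _CODONS_BY_AA[_aa] += (_codon,)
_CODONS_BY_AA = {aa: tuple(sorted(c)) for aa, c in _CODONS_BY_AA.items()}


def _default_cag_prob() -> dict[str, float]:
    # inserted highest, stable at the mammalian 3:1 background, mutated lowest
    return {
        "stable": 0.75,
        "inserted": 0.85,
        "mutated": 0.70,
        "undefined": 0.75,
        "uncategorized": 0.75,
    }


def _default_context_enrichment() -> dict[str, dict[str, dict[int, float]]]:
    # leucine helix-promoting signal at -1 of stable polyQ; proline capping
    # downstream of length-variable (inserted) polyQ
    return {
        "stable": {"L": {-1: 0.3}},
        "inserted": {"P": {k: 0.3 for k in range(1, 11)}},
    }


def _default_interactor_mean() -> dict[str, float]:
    return {
        "stable": 25.0,
        "inserted": 12.0,
        "mutated": 12.0,
        "undefined": 15.0,
        "uncategorized": 15.0,
    }


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate the real setting: 15 species per ortholog set, polyQ
    lengths 6-12, per-category CAG probabilities bracketing the 3:1
    vertebrate background, a leucine -1 enrichment for stable regions and
    a downstream proline enrichment for inserted ones, and higher
    interactor counts for proteins with stable polyQ.
    """

    n_sets: int = 100  # per category
    n_species: int = 15
    categories: tuple[str, ...] = CATEGORY_LABELS
    region_length_range: tuple[int, int] = (6, 12)
    flank_len: int = 30
    extra_flank_range: tuple[int, int] = (0, 150)
    cag_prob: dict[str, float] = field(default_factory=_default_cag_prob)
    context_enrichment: dict[str, dict[str, dict[int, float]]] = field(
        default_factory=_default_context_enrichment
    )
    q_background_weight: float = 0.005
    noise_rate: float = 0.0  # per-region-column perturbation probability
    interactor_mean: dict[str, float] = field(default_factory=_default_interactor_mean)
    missing_links_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.region_length_range[0] < 4:
            raise ValueError("polyQ regions require length >= 4")
        for p in self.cag_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("cag_prob values must lie in [0, 1]")
        unknown = set(self.categories) - set(CATEGORY_LABELS)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted in one synthetic ortholog set."""

    set_id: str
    category: str
    n_species: int
    region_length: int
    col_start: int  # 1-based alignment columns of the planted span
    col_end: int
    cag_prob: float
    protein_length: int  # ungapped length, identical for every row
    q_row_ids: tuple[str, ...]  # rows carrying Q across the whole span


class UnsatisfiableSpecError(ValueError):
    """The requested category band cannot be realized at this row count."""


def _q_count_choices(category: str, n: int) -> list[int]:
    """Admissible per-column glutamine counts for a planted category."""
    lo_unstable = math.ceil(UNCATEGORIZED_THRESHOLD * n)
    hi_unstable = math.ceil(CONSERVED_THRESHOLD * n) - 1
    if category == "stable":
        return list(range(math.ceil(CONSERVED_THRESHOLD * n), n + 1))
    choices = [k for k in range(max(lo_unstable, 1), hi_unstable + 1) if k < n]
    if category == "undefined":
        choices = [k for k in choices if (n - k) % 2 == 0 and n - k >= 2]
    return choices


def _split_remainder(category: str, m: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split the ``m`` non-Q rows into (n_gap, n_other) per the category."""
    if category == "inserted":
        n_other = int(rng.integers(0, (m - 1) // 2 + 1))  # gaps strictly win
        return m - n_other, n_other
    if category == "mutated":
        n_gap = int(rng.integers(0, (m - 1) // 2 + 1))
        return n_gap, m - n_gap
    if category == "undefined":
        return m // 2, m // 2
    # stable: remainder composition is irrelevant to the category
    n_gap = int(rng.integers(0, m + 1))
    return n_gap, m - n_gap


def _draw_background(rng: np.random.Generator, size: int, q_weight: float,
                     exclude: str | None = None) -> list[str]:
    letters = list(_AA20)
    weights = np.full(20, (1.0 - q_weight) / 19.0)
    weights[letters.index("Q")] = q_weight
    if exclude is not None and exclude != "Q":
        weights[letters.index(exclude)] = 0.0
        weights /= weights.sum()
    return list(rng.choice(letters, size=size, p=weights))


def _region_block(
    category: str, n: int, length: int, rng: np.random.Generator
) -> tuple[list[str], set[int]]:
    """Build the region columns for every row; returns (per-row strings, Q rows).

    The same rows carry Q at every column of a block, so member spans
    equal the planted span.  The ``uncategorized`` plant ties one
    conserved half-block against one inserted half-block.
    """

    def pick_rows(k: int) -> set[int]:
        rows = {0}
        others = rng.permutation(np.arange(1, n))[: k - 1]
        return rows | set(int(x) for x in others)

    def block(cat: str, cols: int) -> tuple[list[str], set[int]]:
        choices = _q_count_choices(cat, n)
        if not choices:
            raise UnsatisfiableSpecError(
                f"category {cat!r} cannot be planted with n_species={n}"
            )
        n_q = int(rng.choice(choices))
        q_rows = pick_rows(n_q)
        n_gap, n_other = _split_remainder(cat, n - n_q, rng)
        rest = [r for r in range(n) if r not in q_rows]
        rng.shuffle(rest)
        gap_rows = set(rest[:n_gap])
        per_row = []
        for r in range(n):
            if r in q_rows:
                per_row.append("Q" * cols)
            elif r in gap_rows:
                per_row.append(GAP * cols)
            else:
                per_row.append("".join(rng.choice(list(_NON_Q), size=cols)))
        return per_row, q_rows

    if category != "uncategorized":
        return block(category, length)
    half = length // 2
    left, q_left = block("stable", half)
    right, q_right = block("inserted", length - half)
    per_row = [a + b for a, b in zip(left, right)]
    # only rows with Q across the full span are guaranteed full-span members
    return per_row, q_left & q_right


def _apply_noise(
    region_rows: list[str], noise_rate: float, rng: np.random.Generator
) -> list[str]:
    if noise_rate <= 0:
        return region_rows
    n = len(region_rows)
    length = len(region_rows[0])
    grid = [list(s) for s in region_rows]
    for col in range(length):
        if rng.random() < noise_rate:
            r = int(rng.integers(n))
            kind = int(rng.integers(3))
            grid[r][col] = (
                "Q" if kind == 0 else GAP if kind == 1 else str(rng.choice(list(_NON_Q)))
            )
    return ["".join(row) for row in grid]


def generate_ortholog_set(
    spec: SyntheticSpec,
    category: str,
    seed: int | np.random.Generator,
    set_id: str = "synthetic",
    with_cds: bool = True,
    max_retries: int = 50,
) -> tuple[OrthologAlignment, list[CdsRecord], GroundTruth]:
    """Generate one aligned ortholog set with a single planted polyQ region.

    Regenerates (bounded retries) if the low-weight glutamine background
    accidentally produces a polyQ outside the planted span.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if category not in CATEGORY_LABELS:
        raise ValueError(f"unknown category {category!r}")
    n = spec.n_species
    lo, hi = spec.region_length_range
    for _ in range(max_retries):
        length = int(rng.integers(lo, hi + 1))
        if category == "uncategorized" and length % 2:
            length += 1
        region_rows, q_rows = _region_block(category, n, length, rng)
        region_rows = _apply_noise(region_rows, spec.noise_rate, rng)
        base_right = spec.flank_len + int(
            rng.integers(spec.extra_flank_range[0], spec.extra_flank_range[1] + 1)
        )
        enrich = spec.context_enrichment.get(category, {})
        rows: list[SequenceRecord] = []
        max_right_cols = base_right + length
        for r in range(n):
            left = _flank(rng, spec, enrich, spec.flank_len, side="left")
            n_gaps = region_rows[r].count(GAP)
            right = _flank(rng, spec, enrich, base_right + n_gaps, side="right")
            pad = GAP * (max_right_cols - len(right))
            rows.append(
                SequenceRecord(
                    id=f"{set_id}_sp{r:02d}",
                    species=f"species_{r:02d}",
                    residues=left + region_rows[r] + right + pad,
                )
            )
        alignment = OrthologAlignment(set_id=set_id, rows=rows)
        if _only_planted_region(alignment, spec.flank_len, spec.flank_len + length):
            break
    else:
        raise RuntimeError(f"{set_id}: could not avoid accidental polyQ in flanks")

    truth = GroundTruth(
        set_id=set_id,
        category=category,
        n_species=n,
        region_length=length,
        col_start=spec.flank_len + 1,
        col_end=spec.flank_len + length,
        cag_prob=spec.cag_prob.get(category, 0.75),
        protein_length=spec.flank_len + length + base_right,
        q_row_ids=tuple(rows[r].id for r in sorted(q_rows)),
    )
    cds = _emit_cds(alignment, truth.cag_prob, rng) if with_cds else []
    return alignment, cds, truth


def _flank(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    enrich: Mapping[str, Mapping[int, float]],
    size: int,
    side: str,
) -> str:
    """Background flank with exact planted per-offset enrichments.

    Offsets are -1.. -size (left, innermost residue is -1) or +1..+size
    (right).  An enriched offset places the residue with its stated
    probability and otherwise draws from the background *excluding* it,
    so the planted probability is exact.
    """
    chars = _draw_background(rng, size, spec.q_background_weight)
    for residue, by_offset in enrich.items():
        for offset, p in by_offset.items():
            if side == "left" and offset < 0 and -offset <= size:
                idx = size + offset
            elif side == "right" and offset > 0 and offset <= size:
                idx = offset - 1
            else:
                continue
            if rng.random() < p:
                chars[idx] = residue
            else:
                chars[idx] = _draw_background(rng, 1, spec.q_background_weight, exclude=residue)[0]
    return "".join(chars)


def _only_planted_region(
    alignment: OrthologAlignment, col_start0: int, col_end0: int
) -> bool:
    """True when every detected polyQ lies inside the planted column span.

    A glutamine drawn into a flank adjacent to the region would extend the
    detected span beyond the plant; such sets are regenerated so that the
    planted span is exact.
    """
    from .seq_io import build_column_map

    cmap = build_column_map(alignment)
    for row in alignment.rows:
        r2c = cmap.res_to_col[row.id]
        for reg in scan_polyq(row.ungapped(), row_id=row.id):
            a, b = r2c[reg.start_res - 1], r2c[reg.end_res - 1]
            if a < col_start0 or b >= col_end0:
                return False
    return True


def _emit_cds(
    alignment: OrthologAlignment, cag_prob: float, rng: np.random.Generator
) -> list[CdsRecord]:
    records = []
    for row in alignment.rows:
        codons = []
        for aa in row.ungapped():
            if aa == "Q":
                codons.append("CAG" if rng.random() < cag_prob else "CAA")
            else:
                codons.append(str(rng.choice(_CODONS_BY_AA[aa])))
        records.append(CdsRecord(id=row.id, codons=tuple(codons)))
    return records


def generate_graded_set(
    spec: SyntheticSpec,
    q_conservation: float,
    seed: int | np.random.Generator,
    set_id: str = "graded",
) -> OrthologAlignment:
    """Generate a set whose category *emerges* from a conservation level.

    Unlike the planted constructions, each region column draws its
    glutamine count from Binomial(n - 1, q_conservation) (plus the
    always-Q row 0), with the non-Q remainder split at random between
    gaps and substitutions.  High conservation therefore yields mostly
    conserved columns and stable regions; low conservation yields
    unstable ones — the "more similar orthologs mean more stable polyQ"
    relation, without fixing the outcome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0.0 <= q_conservation <= 1.0:
        raise ValueError("q_conservation must lie in [0, 1]")
    n = spec.n_species
    lo, hi = spec.region_length_range
    length = int(rng.integers(lo, hi + 1))
    grid = [["Q"] * length]  # row 0 carries the detectable tract
    for _ in range(1, n):
        grid.append([])
    for col in range(length):
        has_q = rng.random(n - 1) < q_conservation
        for r in range(1, n):
            if has_q[r - 1]:
                grid[r].append("Q")
            elif rng.random() < 0.5:
                grid[r].append(GAP)
            else:
                grid[r].append(str(rng.choice(list(_NON_Q))))
    rows = []
    base_right = spec.flank_len
    for r in range(n):
        block = "".join(grid[r])
        left = "".join(_draw_background(rng, spec.flank_len, spec.q_background_weight))
        right = "".join(
            _draw_background(rng, base_right + block.count(GAP), spec.q_background_weight)
        )
        pad = GAP * (base_right + length - len(right))
        rows.append(
            SequenceRecord(
                id=f"{set_id}_sp{r:02d}",
                species=f"species_{r:02d}",
                residues=left + block + right + pad,
            )
        )
    return OrthologAlignment(set_id=set_id, rows=rows)


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    overwrite: bool = False,
    with_cds: bool = True,
    with_links: bool = True,
) -> list[GroundTruth]:
    """Write a full synthetic dataset: alignments, CDS, links and manifest.

    Produces ``n_sets`` alignments per category under ``alignments/``
    (and matching ``cds/`` files), a STRING-style ``links.tsv``, a
    ``protein_lengths.tsv`` and a machine-readable ``manifest.tsv`` /
    ``manifest.json`` recording the planted ground truth.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out}: output directory not empty (pass overwrite=True)")
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    if with_cds:
        (out / "cds").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truths: list[GroundTruth] = []
    link_lines: list[str] = []
    length_lines: list[str] = []
    hub_pool = [f"HUB{i:05d}" for i in range(5000)]
    for category in spec.categories:
        for i in range(spec.n_sets):
            set_id = f"{category}_{i:04d}"
            alignment, cds, truth = generate_ortholog_set(
                spec, category, rng, set_id=set_id, with_cds=with_cds
            )
            truths.append(truth)
            write_alignment_fasta(alignment, out / "alignments" / f"{set_id}.fasta")
            if with_cds:
                _write_cds_fasta(cds, out / "cds" / f"{set_id}.fasta")
            if with_links:
                mean = spec.interactor_mean.get(category, 15.0)
                for row in alignment.rows:
                    length_lines.append(f"{row.id}\t{len(row.ungapped())}")
                    if rng.random() < spec.missing_links_frac:
                        continue  # emulate proteins missing from the database
                    k = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
                    partners = rng.choice(len(hub_pool), size=k, replace=False)
                    for h in partners:
                        score = 0.701 + 0.298 * rng.random()
                        link_lines.append(f"{row.id}\t{hub_pool[int(h)]}\t{score:.3f}")
                    # one sub-threshold distractor edge
                    link_lines.append(
                        f"{row.id}\t{hub_pool[int(rng.integers(len(hub_pool)))]}\t{0.1 + 0.6 * rng.random():.3f}"
                    )
    if with_links:
        (out / "links.tsv").write_text(
            "protein1\tprotein2\tcombined_score\n" + "\n".join(link_lines) + "\n"
        )
        (out / "protein_lengths.tsv").write_text(
            "protein_id\tlength\n" + "\n".join(length_lines) + "\n"
        )
    _write_manifest(truths, out)
    logger.info("generate_dataset: wrote %d set(s) to %s", len(truths), out)
    return truths


def _write_cds_fasta(records: Sequence[CdsRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{''.join(rec.codons)}\n")


def _write_manifest(truths: Sequence[GroundTruth], out: Path) -> None:
    header = (
        "set_id\tcategory\tn_species\tregion_length\tcol_start\tcol_end"
        "\tcag_prob\tprotein_length\tq_row_ids"
    )
    lines = [header]
    for t in truths:
        lines.append(
            f"{t.set_id}\t{t.category}\t{t.n_species}\t{t.region_length}"
            f"\t{t.col_start}\t{t.col_end}\t{t.cag_prob}\t{t.protein_length}"
            f"\t{','.join(t.q_row_ids)}"
        )
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
    (out / "manifest.json").write_text(
        json.dumps([t.__dict__ for t in truths], default=list, indent=1) + "\n"
    )
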