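"""Protein-protein interaction capacity of polyQ-bearing proteins.

Interactor counts come from a STRING-style links table (protein1,
protein2, combined_score); only high-confidence partners (score strictly
above 0.7, or 700 on STRING's integer 0-1000 file scale, auto-detected)
are counted, undirected and deduplicated.  Every protein in a categorized
ortholog set inherits the set's region category — whether or not its own
sequence carries the polyQ — and proteins absent from the links table are
dropped rather than zero-filled, since a missing entry cannot be
distinguished from a protein with no interactors.

Protein length is compared alongside the counts as a control: longer
proteins tend to have more interactors, so a count difference is only
interpretable if the length distributions do not differ.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import mannwhitneyu

from .codon_usage import star_bin

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.7
_HEADER_TOKENS = {"protein1", "protein2", "combined_score", "score"}


def parse_links(
    path: str | Path, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> dict[str, set[str]]:
    """Parse a links table into per-protein high-confidence partner sets.

    Rows are whitespace/tab separated: protein1, protein2, combined_score.
    If any score exceeds 1 the file is taken to use STRING's integer
    0-1000 convention and scores are divided by 1000 before the strict
    ``> threshold`` comparison.  Malformed rows are skipped with a
    warning; an empty file is fatal.
    """
    path = Path(path)
    triples: list[tuple[str, str, float]] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and any(p.lower() in _HEADER_TOKENS for p in parts):
                continue
            if len(parts) < 3:
                n_bad += 1
                logger.warning("%s:%d: malformed row skipped: %r", path, lineno, line.rstrip())
                continue
            try:
                score = float(parts[2])
            except ValueError:
                n_bad += 1
                logger.warning("%s:%d: non-numeric score skipped: %r", path, lineno, line.rstrip())
                continue
            triples.append((parts[0], parts[1], score))
    if not triples:
        raise ValueError(f"{path}: no link rows")
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s)", path, n_bad)
    scale = 1000.0 if max(t[2] for t in triples) > 1.0 else 1.0
    partners: dict[str, set[str]] = {}
    for a, b, score in triples:
        if score / scale > threshold:
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
    return partners


def attach_categories(
    partners: Mapping[str, set[str]],
    category_by_protein: Mapping[str, Sequence[str]],
    protein_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Build the (protein, category, n_interactors, protein_length) table.

    ``category_by_protein`` maps protein id -> one category label per polyQ
    region in its ortholog set; a protein in several regions yields one
    row per region (logged).  Proteins without a links-table entry are
    excluded.
    """
    rows = []
    n_multi = n_missing = 0
    for pid, cats in category_by_protein.items():
        if pid not in partners:
            n_missing += 1
            continue
        if len(cats) > 1:
            n_multi += 1
        for cat in cats:
            rows.append(
                {
                    "protein_id": pid,
                    "category": cat,
                    "n_interactors": len(partners[pid]),
                    "protein_length": int(protein_lengths[pid]),
                }
            )
    if n_missing:
        logger.info("attach_categories: %d protein(s) absent from links table, dropped", n_missing)
    if n_multi:
        logger.info("attach_categories: %d multi-region protein(s) duplicated per region", n_multi)
    return pd.DataFrame(
        rows, columns=["protein_id", "category", "n_interactors", "protein_length"]
    )


def compare_counts_and_lengths(table: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney U per category pair, for interactor counts and lengths.

    Returns a tidy frame with one row per (variable, pair): variable is
    ``n_interactors`` or ``protein_length``; stars use the usual bins.
    """
    cats = sorted(table["category"].unique())
    rows = []
    for variable in ("n_interactors", "protein_length"):
        for a, b in itertools.combinations(cats, 2):
            xa = table.loc[table["category"] == a, variable].to_numpy()
            xb = table.loc[table["category"] == b, variable].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("%s: %s vs %s skipped, group too small", variable, a, b)
                continue
            res = mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                {
                    "variable": variable,
                    "group1": a,
                    "group2": b,
                    "n1": len(xa),
                    "n2": len(xb),
                    "u_statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "stars": star_bin(float(res.pvalue)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variable", "group1", "group2", "n1", "n2", "u_statistic", "p_value", "stars"],
    )
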