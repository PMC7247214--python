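"""Glutamine codon usage (%CAG) within orthologous polyQ regions.

CAG tracts expand by replication slippage, so length-variable (inserted)
polyQ regions are expected to show an elevated CAG fraction relative to
the proteome background (about 3:1 CAG:CAA in mammals).  For each
orthologous region, every glutamine whose alignment column falls inside
the region span contributes its codon, pooled over all member rows with a
validated CDS — including rows whose own sequence does not form a polyQ
there, since those glutamines sit in a polyQ context in at least one
ortholog.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import mannwhitneyu

from .seq_io import ColumnMap, CdsPairing, OrthologAlignment
from .stability import StabilityCategory
from .polyq_detect import OrthologousPolyQRegion

logger = logging.getLogger(__name__)

#: significance star bins for Mann-Whitney p-values
STAR_BINS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_bin(p: float) -> str:
    for cutoff, stars in STAR_BINS:
        if p <= cutoff:
            return stars
    return "ns"


@dataclass(frozen=True)
class RegionCodonUsage:
    """Pooled glutamine codon counts for one orthologous region."""

    set_id: str
    col_start: int
    col_end: int
    n_cag: int
    n_caa: int
    category: StabilityCategory | None = None

    @property
    def n_q_codons(self) -> int:
        return self.n_cag + self.n_caa

    @property
    def reportable(self) -> bool:
        return self.n_q_codons >= 1

    @property
    def pct_cag(self) -> float:
        if not self.reportable:
            return float("nan")
        return 100.0 * self.n_cag / self.n_q_codons


@dataclass(frozen=True)
class BackgroundCodonUsage:
    """CAG/CAA counts over every glutamine in a CDS corpus."""

    scope: str
    n_cag: int
    n_caa: int

    @property
    def pct_cag(self) -> float:
        return 100.0 * self.n_cag / (self.n_cag + self.n_caa)


def region_cag_fraction(
    region: OrthologousPolyQRegion,
    alignment: OrthologAlignment,
    column_map: ColumnMap,
    pairing: CdsPairing,
    category: StabilityCategory | None = None,
) -> RegionCodonUsage:
    """Pool CAG/CAA counts over all Q residues at the region's columns.

    Rows without a validated CDS are skipped.  A region with an empty
    codon pool is returned non-reportable and should be excluded from
    distribution-level summaries.
    """
    n_cag = n_caa = 0
    for row in alignment.rows:
        cds = pairing.valid.get(row.id)
        if cds is None:
            continue
        c2r = column_map.col_to_res[row.id]
        for col in range(region.col_start - 1, region.col_end):
            res = c2r.get(col)
            if res is None:
                continue
            if row.residues[col] == "Q":
                codon = cds.codons[res]
                if codon == "CAG":
                    n_cag += 1
                elif codon == "CAA":
                    n_caa += 1
                # other codons impossible under the pairing contract
    usage = RegionCodonUsage(
        set_id=region.set_id,
        col_start=region.col_start,
        col_end=region.col_end,
        n_cag=n_cag,
        n_caa=n_caa,
        category=category,
    )
    if not usage.reportable:
        logger.info(
            "region %s:%d-%d: no glutamine codons in any paired row; non-reportable",
            region.set_id,
            region.col_start,
            region.col_end,
        )
    return usage


def background_cag_fraction(
    pairings: Sequence[tuple[OrthologAlignment, CdsPairing]],
    scope: str = "corpus",
) -> BackgroundCodonUsage:
    """%CAG over every glutamine in every paired protein, polyQ or not."""
    n_cag = n_caa = 0
    for alignment, pairing in pairings:
        for row in alignment.rows:
            cds = pairing.valid.get(row.id)
            if cds is None:
                continue
            for aa, codon in zip(row.ungapped(), cds.codons):
                if aa == "Q":
                    if codon == "CAG":
                        n_cag += 1
                    elif codon == "CAA":
                        n_caa += 1
    if n_cag + n_caa == 0:
        raise ValueError("background_cag_fraction: no glutamines in the corpus")
    return BackgroundCodonUsage(scope=scope, n_cag=n_cag, n_caa=n_caa)


def compare_category_distributions(
    values_by_category: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test for every pair of categories.

    Returns a table with one row per pair: group sizes, the U statistic,
    the p-value, and the conventional significance stars
    (**** <= 1e-4, *** <= 1e-3, ** <= 0.01, * <= 0.05, ns otherwise).
    Pairs involving a group with fewer than two values are skipped.
    """
    rows = []
    for a, b in itertools.combinations(values_by_category, 2):
        xa, xb = list(values_by_category[a]), list(values_by_category[b])
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("comparison %s vs %s skipped: group too small", a, b)
            continue
        res = mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
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
        rows, columns=["group1", "group2", "n1", "n2", "u_statistic", "p_value", "stars"]
    )
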