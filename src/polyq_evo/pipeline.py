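"""End-to-end orchestration: scan -> categorize -> codon/context/interactions.

Runs the whole analysis over a directory of aligned ortholog sets (one
FASTA per set), with optional CDS, links-table and secondary-structure
inputs, and writes one TSV per stage plus a JSON summary.  All stage
outputs are kept in memory until every stage has finished, so a fatal
error in any stage leaves no partial result files behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import codon_usage as cu
from . import context as ctx
from . import interactions as ppi
from .polyq_detect import filter_sets
from .seq_io import (
    OrthologAlignment,
    build_column_map,
    pair_cds_with_protein,
    read_alignment_fasta,
    read_cds_fasta,
)
from .stability import (
    CONSERVED_THRESHOLD,
    ColumnSubvalue,
    ColumnValue,
    RegionCategorization,
    StabilityCategory,
    UNCATEGORIZED_THRESHOLD,
    categorize_alignment,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Fatal pipeline failure, tagged with the stage that raised it."""


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Defaults are the study parameters: 4-in-6 detection, >= 80% / < 20%
    column conservation thresholds, minimum five species per set, links
    score > 0.7, context flank 10 and structure flank 20.  Categories 4
    (undefined) and 5 (uncategorized) are excluded from downstream
    analyses unless ``keep_uninformative`` is set.
    """

    alignments_dir: str | Path = "."
    out_dir: str | Path = "polyq_out"
    cds_dir: str | Path | None = None
    links_path: str | Path | None = None
    ss_path: str | Path | None = None
    min_q: int = 4
    window: int = 6
    conserved_threshold: float = CONSERVED_THRESHOLD
    uncategorized_threshold: float = UNCATEGORIZED_THRESHOLD
    min_rows: int = 5
    links_threshold: float = 0.7
    flank: int = 10
    ss_flank: int = 20
    context_residues: tuple[str, ...] = ("L", "P")
    keep_uninformative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.uncategorized_threshold < self.conserved_threshold <= 1:
            raise ValueError("need 0 <= uncategorized < conserved <= 1")
        if self.min_q > self.window:
            raise ValueError("min_q cannot exceed window")


@dataclass
class RunResult:
    """In-memory bundle of every stage's output tables."""

    regions: pd.DataFrame
    codon_usage: pd.DataFrame | None
    codon_comparisons: pd.DataFrame | None
    context_profiles: pd.DataFrame | None
    structure_profiles: pd.DataFrame | None
    interactors: pd.DataFrame | None
    interaction_comparisons: pd.DataFrame | None
    summary: dict
    structure_windows: list = field(default_factory=list)


def _load_alignments(config: RunConfig) -> list[OrthologAlignment]:
    adir = Path(config.alignments_dir)
    paths = sorted(p for p in adir.glob("*") if p.suffix in {".fasta", ".fa", ".faa"})
    if not paths:
        raise PipelineError(f"[input] no input sets in {adir}")
    return [read_alignment_fasta(p) for p in paths]


def _region_row(set_id: str, rc: RegionCategorization) -> dict:
    return {
        "set_id": set_id,
        "col_start": rc.region.col_start,
        "col_end": rc.region.col_end,
        "n_members": rc.region.n_members,
        "n_conserved": rc.count(ColumnValue.CONSERVED),
        "n_unstable": rc.count(ColumnValue.UNSTABLE),
        "n_inserted": rc.subcount(ColumnSubvalue.INSERTED),
        "n_mutated": rc.subcount(ColumnSubvalue.MUTATED),
        "n_undefined": rc.subcount(ColumnSubvalue.UNDEFINED),
        "category_code": int(rc.category),
        "category": rc.category.label,
    }


def run_all(config: RunConfig, write: bool = True) -> RunResult:
    """Execute every applicable stage and (optionally) write results.

    Stages whose inputs were not supplied (CDS, links, structure strings)
    are skipped; their tables are ``None`` in the result.
    """
    rng = np.random.default_rng(config.seed)

    # -- detection + categorization ------------------------------------
    try:
        alignments = _load_alignments(config)
        kept = filter_sets(alignments, min_rows=config.min_rows)
        if not kept:
            raise PipelineError("[categorize] no input sets after the min-rows filter")
        cmaps = {a.set_id: build_column_map(a) for a in kept}
        categorized: list[tuple[OrthologAlignment, RegionCategorization]] = []
        for a in kept:
            for rc in categorize_alignment(
                a,
                column_map=cmaps[a.set_id],
                min_q=config.min_q,
                window=config.window,
                conserved_threshold=config.conserved_threshold,
                uncategorized_threshold=config.uncategorized_threshold,
            ):
                categorized.append((a, rc))
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive re-tagging
        raise PipelineError(f"[categorize] {exc}") from exc

    regions = pd.DataFrame(
        [_region_row(a.set_id, rc) for a, rc in categorized],
        columns=list(_region_row("", categorized[0][1]).keys()) if categorized else None,
    )
    informative = [
        (a, rc) for a, rc in categorized
        if config.keep_uninformative or rc.category.informative
    ]
    n_discarded = len(categorized) - len(informative)

    # -- codon usage ----------------------------------------------------
    codon_table = codon_cmp = None
    background = None
    if config.cds_dir is not None:
        try:
            pairings = {}
            for a, _ in categorized:
                if a.set_id in pairings:
                    continue
                cds_path = Path(config.cds_dir) / f"{a.set_id}.fasta"
                if cds_path.exists():
                    pairings[a.set_id] = pair_cds_with_protein(a, read_cds_fasta(cds_path))
            rows = []
            by_cat: dict[str, list[float]] = {}
            for a, rc in informative:
                pairing = pairings.get(a.set_id)
                if pairing is None:
                    continue
                usage = cu.region_cag_fraction(
                    rc.region, a, cmaps[a.set_id], pairing, category=rc.category
                )
                if usage.reportable:
                    rows.append(
                        {
                            "set_id": usage.set_id,
                            "col_start": usage.col_start,
                            "col_end": usage.col_end,
                            "category": rc.category.label,
                            "n_cag": usage.n_cag,
                            "n_caa": usage.n_caa,
                            "pct_cag": usage.pct_cag,
                        }
                    )
                    by_cat.setdefault(rc.category.label, []).append(usage.pct_cag)
            codon_table = pd.DataFrame(
                rows,
                columns=["set_id", "col_start", "col_end", "category", "n_cag", "n_caa", "pct_cag"],
            )
            codon_cmp = cu.compare_category_distributions(by_cat)
            paired = [(a, pairings[a.set_id]) for a, _ in categorized if a.set_id in pairings]
            # one alignment may carry several regions; deduplicate by set
            seen: set[str] = set()
            paired = [
                (a, p) for a, p in paired if not (a.set_id in seen or seen.add(a.set_id))
            ]
            if paired:
                background = cu.background_cag_fraction(paired, scope="input batch")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[codon-usage] {exc}") from exc

    # -- amino-acid context + structure windows -------------------------
    context_table = structure_table = None
    windows = []
    try:
        reps = [
            ctx.select_representative(rc.region, a, rng, category=rc.category)
            for a, rc in informative
        ]
        if reps:
            corpus = [
                row.ungapped() for a in {id(a): a for a, _ in informative}.values()
                for row in a.rows
            ]
            crows = []
            for residue in config.context_residues:
                bg = ctx.background_frequency(corpus, residue)
                for cat in sorted({r.category.label for r in reps}):
                    sub = [r for r in reps if r.category.label == cat]
                    prof = ctx.residue_context_profile(sub, residue, flank=config.flank)
                    for pos in prof.positions:
                        crows.append(
                            {
                                "residue": residue,
                                "category": cat,
                                "position": pos,
                                "count": prof.counts[pos],
                                "n": prof.n_samples[pos],
                                "freq": prof.freq(pos),
                                "background": bg,
                            }
                        )
            context_table = pd.DataFrame(
                crows,
                columns=["residue", "category", "position", "count", "n", "freq", "background"],
            )
            windows = ctx.extract_structure_windows(reps, flank=config.ss_flank)
            if config.ss_path is not None:
                ss_strings = {
                    rec.id: str(rec.seq) for rec in SeqIO.parse(str(config.ss_path), "fasta")
                }
                structure_table = ctx.aggregate_structure(
                    windows, ss_strings, flank=config.flank
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[context] {exc}") from exc

    # -- interactions ----------------------------------------------------
    interactor_table = interaction_cmp = None
    if config.links_path is not None:
        try:
            partners = ppi.parse_links(config.links_path, threshold=config.links_threshold)
            category_by_protein: dict[str, list[str]] = {}
            lengths: dict[str, int] = {}
            for a, rc in informative:
                for row in a.rows:
                    category_by_protein.setdefault(row.id, []).append(rc.category.label)
                    lengths[row.id] = len(row.ungapped())
            interactor_table = ppi.attach_categories(partners, category_by_protein, lengths)
            if not interactor_table.empty:
                interaction_cmp = ppi.compare_counts_and_lengths(interactor_table)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[interactors] {exc}") from exc

    # -- summary ----------------------------------------------------------
    counts = {c.label: 0 for c in StabilityCategory}
    for _, rc in categorized:
        counts[rc.category.label] += 1
    summary = {
        "n_sets_input": len(alignments),
        "n_sets_kept": len(kept),
        "n_regions": len(categorized),
        "category_counts": counts,
        "n_discarded_uninformative": n_discarded,
        "background_pct_cag": background.pct_cag if background else None,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }

    result = RunResult(
        regions=regions,
        codon_usage=codon_table,
        codon_comparisons=codon_cmp,
        context_profiles=context_table,
        structure_profiles=structure_table,
        interactors=interactor_table,
        interaction_comparisons=interaction_cmp,
        summary=summary,
        structure_windows=windows,
    )
    if write:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "regions.tsv": result.regions,
        "codon_usage.tsv": result.codon_usage,
        "codon_comparisons.tsv": result.codon_comparisons,
        "context_profiles.tsv": result.context_profiles,
        "structure_profiles.tsv": result.structure_profiles,
        "interactors.tsv": result.interactors,
        "interaction_comparisons.tsv": result.interaction_comparisons,
    }
    for name, table in tables.items():
        if table is not None:
            table.to_csv(out / name, sep="\t", index=False)
    if result.structure_windows:
        ctx.write_windows_fasta(result.structure_windows, out / "ss_windows.fasta")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1) + "\n")
    logger.info("pipeline outputs written to %s", out)
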