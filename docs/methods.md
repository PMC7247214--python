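# Methods

## The model

A polyglutamine (polyQ) region is defined by glutamine density, not
purity: every window of up to `window` consecutive residues (default 6)
containing at least `min_q` glutamines (default 4) marks its positions as
covered; maximal covered runs, trimmed so they begin and end with Q, are
the regions. Windows truncated at the sequence end also qualify, so a
bare 4-residue tract is a polyQ — the 4/6 rule is a density threshold and
excluding short pure tracts would be an artifact of window bookkeeping.
Two consequences worth noting: regions never overlap or touch, and
detection is invariant under appending non-Q flanks. `X` (unknown) counts
as non-glutamine everywhere.

Within an ortholog alignment, per-row regions are projected to alignment
columns and merged by transitive closure of *column-span overlap*.
Touching spans that share no column stay separate, so distinct
orthologous regions never share a column and one alignment may hold
several regions. The span of an orthologous region is the union of its
member spans; classification runs over that merged span, since the
region's evolutionary context is the full aligned block (an intersection
variant would ignore columns where only some members extend).

Each column of the span is classified by the glutamine fraction over
*all* rows of the alignment — a gapped row counts in the denominator,
because a gap is "not having a glutamine" and is precisely the evidence
for length variation:

| column value  | condition                  | sub-value |
|---------------|----------------------------|-----------|
| conserved     | n_Q / n_rows ≥ 0.8         | —         |
| unstable      | 0.2 ≤ n_Q / n_rows < 0.8   | inserted if gaps > substitutions; mutated if substitutions > gaps; undefined on a tie |
| uncategorized | n_Q / n_rows < 0.2         | —         |

The region category is the strict majority over its columns: **stable**
if conserved columns outnumber unstable ones; otherwise **inserted** /
**mutated** if that sub-value strictly dominates both others;
**undefined** if unstable wins but neither mechanism dominates;
**uncategorized** for everything else. Uncategorized columns count
toward neither side, so a span of only uncategorized columns, or any
conserved/unstable tie, falls to category 5. Categories 4 and 5 are
excluded from downstream analyses by default: neither identifies a
mechanism.

## Downstream profiles

**Codon usage.** For each orthologous region, every glutamine whose
column lies in the span contributes its codon, pooled over all member
rows with a validated CDS — including glutamines in rows that do not
themselves form a polyQ there, since they sit in a polyQ context in at
least one ortholog. One %CAG value per region (not per row) keeps the
distributions over region sets; a per-row breakdown is available through
the same counting loop but is not the default. CDS records are paired to
rows by identifier and validated: codon count must equal ungapped residue
count (a terminal stop is dropped first) and every Q must be encoded by
CAA/CAG. Rows failing a check are excluded from codon analyses only,
with logged counts; a region is non-reportable only when its codon pool
is empty.

**Context.** One representative per region is drawn uniformly among the
member rows (which, by construction, carry the polyQ), deterministically
under the run seed. Offsets −10..−1 and +1..+10 are counted in the
representative's *ungapped* sequence; per-position denominators include
only representatives whose sequence reaches that offset (no padding, so
truncated flanks do not dilute frequencies). Background frequencies are
corpus-wide residue fractions with gaps excluded.

**Secondary structure** is consumed, never predicted: windows of the
region ± 20 residues are exported as FASTA for an external predictor, and
the returned one-character-per-residue strings (H → helical, E →
extended, anything else → other) are aggregated per category over
positions −10..+10 only, avoiding border effects in the predictions.
Length-mismatched strings are skipped with a warning.

**Interactions.** Links tables are undirected and deduplicated; only
partners with combined score strictly above 0.7 count (files using the
integer 0–1000 convention are auto-detected — any score above 1 — and
divided by 1000). Proteins inherit the category of their set's region
whether or not their own sequence has the polyQ; multi-region proteins
yield one row per region; proteins absent from the table are dropped, not
zero-filled, because absence is indistinguishable from missingness.
Protein length is compared alongside the counts: a count difference is
only interpretable when lengths do not differ.

**Comparisons** are two-sided Mann–Whitney U tests (scipy), annotated
with the conventional star bins (**** ≤ 1e-4, *** ≤ 1e-3, ** ≤ 0.01,
* ≤ 0.05, ns). Groups with fewer than two values are skipped.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_q` / `window` | 4 / 6 | detection density threshold; the most permissive common definition, maximizing region counts |
| `conserved_threshold` | 0.8 | column Q-fraction bound for "conserved" (inclusive) |
| `uncategorized_threshold` | 0.2 | column Q-fraction bound for "uncategorized" (exclusive) |
| `min_rows` | 5 | minimum species per ortholog set |
| `links_threshold` | 0.7 | strict lower bound on the combined interaction score |
| `flank` / `ss_flank` | 10 / 20 | context offsets; structure window half-width |

All internal coordinates are 0-based half-open; every reported coordinate
is 1-based inclusive.

## The synthetic generator

`synthetic_data` emulates ortholog sets with planted ground truth (the
stand-in for real proteome downloads). Defaults are the study
conditions: 15 species per set, region lengths 6–12, flank length 30 plus
a uniformly drawn 0–150 extension, per-category CAG probabilities
(stable 0.75 — the mammalian 3:1 background — inserted 0.85, mutated
0.70), a leucine enrichment of 0.3 at −1 for stable regions and a proline
enrichment of 0.3 across +1..+10 for inserted ones, and mean interactor
counts of 25 (stable) vs 12 (inserted/mutated).

Construction is column-wise in alignment space. A fixed row subset
(always including row 0, which carries a pure tract and guarantees
detection) has glutamine across the whole span; the remaining rows are
entirely gap or entirely substituted, with per-category counts drawn from
the admissible bands (e.g. for *inserted*, a Q fraction in [0.2, 0.8)
with gaps strictly outnumbering substitutions). The *uncategorized*
plant ties a conserved half-block against an inserted half-block. This
block design makes per-column counts exact, makes every member span equal
the planted span, and keeps the (out-of-scope) aligner out of the test
loop. Optional per-column noise perturbs one random row's state with the
given probability, after which the CDS is derived, so codons always match
residues.

Three deliberate controls: flank backgrounds are uniform over the 20
residues with glutamine down-weighted to 0.005, and any set in which a
stray flank glutamine extends or adds a detected region is regenerated
(bounded, deterministic retries), so the planted span is exact; context
enrichments place the residue with exactly the stated probability and
otherwise draw from a background *excluding* it, so recovery tests check
the exact planted value; and per-row right-flank lengths absorb the row's
gap count, making ungapped protein lengths identical within a set and
category-independent across sets — the length control needed when
interpreting interactor-count differences. A second generator mode
(`generate_graded_set`) does not plant a category at all: per-column Q
counts are binomial at a chosen conservation level, so the stable
fraction rises with ortholog similarity rather than being imposed.

What the generator does **not** emulate: phylogenetic correlation among
rows (rows are exchangeable), slippage dynamics over time, realistic
residue composition, alignment errors, or paralog contamination.
Recovery tests therefore show that the implementation computes its
definitions correctly under controlled conditions — not that the
categories are biologically optimal for real proteomes.

## Numerical and design choices

- Average alignment identity is computed directly from the alignment
  (mean over unordered row pairs of identical columns over columns where
  at least one row has a residue; double-gap columns ignored, gap vs
  residue a mismatch), since pairwise-distance output of an external tool
  is not part of the inputs.
- Strict inequalities at every tie point, following the category
  definitions' "more … than" wording: C = U ties fall to category 5,
  sub-value ties within unstable columns to "undefined".
- The conserved bound is inclusive (a column with exactly 80 % glutamine
  is conserved); the uncategorized bound is exclusive.
- Degenerate inputs are named errors, not silent fixes: ragged or
  duplicate-id alignments, empty columns/region spans, CDS with no id
  overlap, empty links files and empty input directories are fatal;
  individually malformed CDS records or links rows are excluded with
  logged warnings.
- Mann–Whitney with small groups (< 2 values) skips the pair rather than
  reporting an unstable p-value.

## Problem sizes and statistical checks

Recovery tests run 500 synthetic sets per category for categorization
(perfect recovery required on unambiguous plants; ≥ 95 % under 5 %
per-column noise), 200 per category for codon usage and 1,000 per
category for context profiles; planted proportions are accepted within
99 % binomial intervals at the pooled count. The acceptance script uses
200 sets per category and 500 per category for context, sizes at which
the binomial intervals are a few percentage points wide. The
interactor length control is a test of a true null with a built-in 5 %
false-positive rate, so it is evaluated over five independent replicates
(count shift significant in all, length non-significant in the majority),
bringing the false-failure probability to about 1e-3.

## Known limitations

- Categorization depends on the species sampled: more divergent ortholog
  sets shift regions from stable toward inserted/mutated, which is a
  property of the definition, not a defect (`generate_graded_set`
  demonstrates the gradient).
- The secondary-structure stage aggregates external predictions; no
  predictor ships with the package, so that stage is exercised with
  synthetic structure strings only.
- Multi-region proteins contribute one interactor row per region, which
  double-counts their partners across categories; the alternative
  (single-label assignment) is not well defined and was not adopted.
- GO enrichment and ortholog inference/alignment construction are out of
  scope; the pipeline exports per-category protein lists and consumes
  pre-aligned sets.
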