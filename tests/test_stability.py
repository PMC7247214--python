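"""Column classification and five-way region categorization."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from polyq_evo.stability import (
    ColumnClass,
    ColumnSubvalue,
    ColumnValue,
    StabilityCategory,
    categorize_alignment,
    categorize_region,
    classify_column,
)
from polyq_evo.synthetic_data import SyntheticSpec, generate_graded_set
from .conftest import column_rule_oracle, make_alignment, region_rule_oracle


def _column(n_q: int, n_gap: int, n_other: int) -> str:
    return "Q" * n_q + "-" * n_gap + "L" * n_other


class TestClassifyColumn:
    @pytest.mark.parametrize(
        "residues, value, subvalue",
        [
            ("QQQQQQQQAA", "conserved", "none"),  # 8/10 meets the >= 80% bound
            ("QQQQ-----L", "unstable", "inserted"),  # 5 gaps > 1 substitution
            ("QQQQ---LLL", "unstable", "undefined"),  # 3 gaps = 3 substitutions
            ("QAAAAAAAAA", "uncategorized", "none"),  # 1/10 < 20%
            ("QQQQLLL---", "unstable", "undefined"),
            ("QQQQQLLLL-", "unstable", "mutated"),
        ],
    )
    def test_definitional_examples(self, residues, value, subvalue):
        cc = classify_column(residues)
        assert (cc.value.value, cc.subvalue.value) == (value, subvalue)
        assert cc.n_q + cc.n_gap + cc.n_other == cc.n_rows

    def test_empty_column_fatal(self):
        with pytest.raises(ValueError):
            classify_column("")

    def test_x_counts_as_non_glutamine(self):
        cc = classify_column("QQQQXXXXX-")
        assert cc.n_other == 5 and cc.subvalue is ColumnSubvalue.MUTATED

    def test_exhaustive_against_rule_transcription(self):
        """Every (n_Q, n_gap, n_other) composition with <= 15 rows matches
        a direct transcription of the published thresholds."""
        for n in range(2, 16):
            for n_q in range(n + 1):
                for n_gap in range(n - n_q + 1):
                    n_other = n - n_q - n_gap
                    cc = classify_column(_column(n_q, n_gap, n_other))
                    assert (cc.value.value, cc.subvalue.value) == column_rule_oracle(
                        n_q, n_gap, n_other
                    ), (n_q, n_gap, n_other)

    def test_threshold_monotonicity(self):
        """Replacing a gap or substitution by Q never moves the column away
        from conserved."""
        order = {"uncategorized": 0, "unstable": 1, "conserved": 2}
        rng = random.Random(5)
        for _ in range(200):
            n = rng.randint(2, 15)
            n_q = rng.randint(0, n - 1)
            n_gap = rng.randint(0, n - n_q - 1)
            base = classify_column(_column(n_q, n_gap, n - n_q - n_gap))
            # promote one non-Q row to Q
            bumped = classify_column(_column(n_q + 1, max(n_gap - 1, 0),
                                             n - n_q - 1 - max(n_gap - 1, 0)))
            assert order[bumped.value.value] >= order[base.value.value]


def _cc(value: str, subvalue: str = "none") -> ColumnClass:
    counts = {"n_q": 0, "n_gap": 0, "n_other": 0}
    return ColumnClass(
        col=1, n_rows=10, n_q=5, n_gap=3, n_other=2,
        value=ColumnValue(value), subvalue=ColumnSubvalue(subvalue),
    )


class TestCategorizeRegion:
    @pytest.mark.parametrize(
        "columns, expected",
        [
            ([("conserved",), ("conserved",), ("unstable", "inserted")], 1),
            ([("conserved",), ("unstable", "inserted"), ("unstable", "inserted"),
              ("unstable", "mutated")], 2),
            ([("unstable", "inserted"), ("unstable", "mutated")], 4),
            ([("conserved",), ("unstable", "inserted")], 5),  # C = U tie
            ([("uncategorized",), ("uncategorized",), ("conserved",)], 1),
            ([("uncategorized",), ("uncategorized",)], 5),
            ([("unstable", "mutated"), ("unstable", "mutated"), ("unstable", "undefined")], 3),
            ([("unstable", "undefined"), ("unstable", "undefined"), ("unstable", "inserted")], 4),
        ],
    )
    def test_definitional_examples(self, columns, expected):
        classes = [_cc(*c) for c in columns]
        assert categorize_region(classes) == StabilityCategory(expected)

    def test_empty_span_fatal(self):
        with pytest.raises(ValueError):
            categorize_region([])

    def test_enumerated_against_rule_transcription(self):
        """All (C, I, M, D, X) count vectors summing to <= 7 match the
        direct transcription of the category definitions."""
        for total in range(1, 8):
            for c, i, m, d in itertools.product(range(total + 1), repeat=4):
                x = total - c - i - m - d  # uncategorized columns
                if x < 0:
                    continue
                classes = (
                    [_cc("conserved")] * c
                    + [_cc("unstable", "inserted")] * i
                    + [_cc("unstable", "mutated")] * m
                    + [_cc("unstable", "undefined")] * d
                    + [_cc("uncategorized")] * x
                )
                assert int(categorize_region(classes)) == region_rule_oracle(c, i, m, d)


class TestCategorizeAlignment:
    def test_identical_rows_are_stable(self):
        aln = make_alignment(["AAQQQQAA"] * 5)
        (rc,) = categorize_alignment(aln)
        assert rc.category is StabilityCategory.STABLE
        assert (rc.region.col_start, rc.region.col_end) == (3, 6)

    def test_conserved_boundary_at_80_percent(self):
        aln = make_alignment(["AQQQQA"] * 8 + ["A----A"] * 2)
        (rc,) = categorize_alignment(aln)
        assert all(c.value is ColumnValue.CONSERVED for c in rc.columns)
        assert rc.category is StabilityCategory.STABLE

    def test_half_gapped_rows_give_inserted(self):
        aln = make_alignment(["AQQQQA"] * 5 + ["A----A"] * 5)
        (rc,) = categorize_alignment(aln)
        assert rc.category is StabilityCategory.INSERTED

    def test_partition_into_exactly_one_category(self):
        rng = random.Random(11)
        for _ in range(30):
            rows = []
            n_cols = rng.randint(20, 50)
            for _ in range(rng.randint(5, 10)):
                s = "".join(
                    "Q" if rng.random() < 0.3 else
                    "-" if rng.random() < 0.2 else
                    rng.choice("ALPK")
                    for _ in range(n_cols)
                )
                rows.append(s)
            try:
                aln = make_alignment(rows)
            except ValueError:
                continue
            rcs = categorize_alignment(aln)
            counts = {c: 0 for c in StabilityCategory}
            for rc in rcs:
                counts[rc.category] += 1
            assert sum(counts.values()) == len(rcs)

    def test_row_permutation_invariance(self):
        rng = random.Random(13)
        rows = {
            f"r{i}": "".join(rng.choice("QQ-AL") for _ in range(40)) for i in range(8)
        }
        base = [
            (rc.region.col_start, rc.region.col_end, rc.category)
            for rc in categorize_alignment(make_alignment(rows))
        ]
        for _ in range(5):
            items = list(rows.items())
            rng.shuffle(items)
            shuffled = make_alignment(dict(items))
            got = [
                (rc.region.col_start, rc.region.col_end, rc.category)
                for rc in categorize_alignment(shuffled)
            ]
            assert got == base

    def test_higher_conservation_means_more_stable_regions(self):
        """Sets generated at high per-column glutamine conservation yield a
        larger stable fraction than the same generator at low conservation."""
        spec = SyntheticSpec(n_species=15)
        rng = np.random.default_rng(29)

        def stable_fraction(conservation: float) -> float:
            n_stable = n_total = 0
            for i in range(120):
                aln = generate_graded_set(spec, conservation, rng, set_id=f"g{i}")
                for rc in categorize_alignment(aln):
                    n_total += 1
                    n_stable += rc.category is StabilityCategory.STABLE
            return n_stable / n_total

        assert stable_fraction(0.9) > stable_fraction(0.45)
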