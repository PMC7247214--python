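"""Amino-acid and secondary-structure context around polyQ regions."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from scipy.stats import binom

from polyq_evo.context import (
    Representative,
    StructureWindow,
    aggregate_structure,
    background_frequency,
    extract_structure_windows,
    residue_context_profile,
    select_representative,
)
from polyq_evo.polyq_detect import extract_orthologous_regions
from polyq_evo.stability import StabilityCategory
from .conftest import make_alignment


def _rep(seq: str, start: int, end: int, uid: str = "r", cat=None) -> Representative:
    return Representative(
        set_id="s", row_id=uid, sequence=seq, start_res=start, end_res=end, category=cat
    )


class TestSelectRepresentative:
    def test_single_member_always_chosen(self):
        aln = make_alignment({"a": "AQQQQA", "b": "AAAAAA"})
        (region,) = extract_orthologous_regions(aln)
        rep = select_representative(region, aln, np.random.default_rng(0))
        assert rep.row_id == "a"
        assert (rep.start_res, rep.end_res) == (2, 5)
        assert rep.sequence == "AQQQQA"

    def test_deterministic_given_seed(self):
        aln = make_alignment({"a": "QQQQ", "b": "QQQQ", "c": "QQQQ"})
        (region,) = extract_orthologous_regions(aln)
        picks1 = [
            select_representative(region, aln, np.random.default_rng(s)).row_id
            for s in range(20)
        ]
        picks2 = [
            select_representative(region, aln, np.random.default_rng(s)).row_id
            for s in range(20)
        ]
        assert picks1 == picks2
        assert set(picks1) <= {"a", "b", "c"}

    def test_uniform_over_members(self):
        aln = make_alignment({"a": "QQQQ", "b": "QQQQ"})
        (region,) = extract_orthologous_regions(aln)
        rng = np.random.default_rng(123)
        picks = [select_representative(region, aln, rng).row_id for _ in range(10_000)]
        frac_a = picks.count("a") / len(picks)
        assert abs(frac_a - 0.5) < 0.02


class TestResidueContextProfile:
    def test_flanking_residues_counted_at_correct_offsets(self):
        prof_l = residue_context_profile([_rep("LQQQQP", 2, 5)], "L")
        assert prof_l.freq(-1) == 1.0
        prof_p = residue_context_profile([_rep("LQQQQP", 2, 5)], "P")
        assert prof_p.freq(1) == 1.0
        assert prof_p.freq(-1) == 0.0

    def test_region_at_terminus_skips_missing_positions(self):
        prof = residue_context_profile([_rep("QQQQAP", 1, 4)], "P")
        assert all(prof.n_samples[p] == 0 for p in range(-10, 0))
        assert prof.n_samples[1] == 1 and prof.n_samples[2] == 1
        assert prof.n_samples[3] == 0
        assert math.isnan(prof.freq(-1))

    def test_empty_representative_set_fatal(self):
        with pytest.raises(ValueError):
            residue_context_profile([], "L")

    def test_planted_probability_recovered(self):
        """P(L at -1) = 0.3 planted over 1,000 representatives is recovered
        within the 99% binomial interval."""
        rng = random.Random(31)
        reps = []
        for i in range(1000):
            left = "".join(rng.choice("ACDEFG") for _ in range(10))
            minus1 = "L" if rng.random() < 0.3 else rng.choice("ACDEFG")
            seq = left + minus1 + "QQQQQQ" + "".join(rng.choice("ACDEFG") for _ in range(10))
            reps.append(_rep(seq, 12, 17, uid=f"r{i}"))
        prof = residue_context_profile(reps, "L")
        lo, hi = binom.interval(0.99, 1000, 0.3)
        assert lo <= prof.counts[-1] <= hi
        assert prof.n_samples[-1] == 1000


class TestBackgroundFrequency:
    def test_pure_corpus(self):
        assert background_frequency(["LLLL"], "L") == 1.0

    def test_even_split(self):
        assert background_frequency(["LP"], "L") == 0.5

    def test_gaps_excluded(self):
        assert background_frequency(["L-P-"], "L") == 0.5

    def test_uniform_corpus_close_to_one_twentieth(self):
        rng = random.Random(9)
        corpus = ["".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(10_000))
                  for _ in range(20)]
        freq = background_frequency(corpus, "L")
        assert abs(freq - 0.05) < 0.005


class TestStructureWindows:
    def test_interior_region_window_arithmetic(self):
        rep = _rep("A" * 24 + "QQQQQQ" + "A" * 70, 25, 30)
        (w,) = extract_structure_windows([rep], flank=20)
        # window covers residues 5..50 (1-based)
        assert len(w.sequence) == 46
        assert (w.region_start, w.region_end) == (20, 25)

    def test_left_truncated_window(self):
        rep = _rep("AA" + "QQQQQQ" + "A" * 40, 3, 8)
        (w,) = extract_structure_windows([rep], flank=20)
        assert w.region_start == 2  # only two residues available upstream
        assert len(w.sequence) == 2 + 6 + 20

    def test_symmetric_window_in_centered_construct(self):
        rep = _rep("A" * 41 + "QQQQQQ" + "A" * 41, 42, 47)
        (w,) = extract_structure_windows([rep], flank=20)
        assert (w.region_start, len(w.sequence) - 1 - w.region_end) == (20, 20)


class TestAggregateStructure:
    def _window(self, uid, cat=StabilityCategory.STABLE):
        seq = "A" * 15 + "QQQQQQ" + "A" * 15
        return StructureWindow(
            uid=uid, sequence=seq, region_start=15, region_end=20, category=cat
        )

    def test_all_helical(self):
        w = self._window("w1")
        table = aggregate_structure([w], {"w1": "H" * len(w.sequence)})
        assert (table["helical"] == 1.0).all()
        assert set(table["position"]) == set(range(-10, 0)) | set(range(1, 11))

    def test_half_helical_half_extended(self):
        w1, w2 = self._window("w1"), self._window("w2")
        ss_h = "H" * len(w1.sequence)
        ss_e = "E" * len(w2.sequence)
        table = aggregate_structure([w1, w2], {"w1": ss_h, "w2": ss_e})
        row = table[table["position"] == -1].iloc[0]
        assert (row["helical"], row["extended"], row["other"]) == (0.5, 0.5, 0.0)

    def test_mismatched_string_skipped(self, caplog):
        w = self._window("w1")
        with caplog.at_level("WARNING"):
            table = aggregate_structure([w], {"w1": "HHH"})
        assert table.empty
        assert "skipped" in caplog.text

    def test_proportions_sum_to_one_on_random_input(self):
        rng = random.Random(2)
        windows, ss = [], {}
        for i in range(40):
            w = self._window(f"w{i}",
                             cat=rng.choice(list(StabilityCategory)))
            windows.append(w)
            ss[w.uid] = "".join(rng.choice("HEC-G") for _ in range(len(w.sequence)))
        table = aggregate_structure(windows, ss)
        assert np.allclose(table["helical"] + table["extended"] + table["other"], 1.0)
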