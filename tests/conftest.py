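"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive expected behaviour by brute force
(window enumeration, direct rule transcription) so they stay independent
of the implementation paths they check.
"""

from __future__ import annotations

import random

import pytest

from polyq_evo.seq_io import OrthologAlignment, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_polyq(seq: str, min_q: int = 4, window: int = 6) -> list[tuple[int, int, str]]:
    """Window-enumeration oracle for polyQ detection.

    Marks every position covered by any window (truncated at the end of
    the sequence) holding >= min_q glutamines, takes maximal covered
    runs, trims them to terminal Q, and reports 1-based (start, end, seq).
    """
    s = seq.upper()
    n = len(s)
    covered = set()
    for i in range(n):
        win = s[i : i + window]
        if win.count("Q") >= min_q:
            covered.update(range(i, min(i + window, n)))
    regions = []
    run: list[int] = []
    for pos in range(n + 1):
        if pos in covered:
            run.append(pos)
            continue
        if run:
            a, b = run[0], run[-1]
            while a <= b and s[a] != "Q":
                a += 1
            while b >= a and s[b] != "Q":
                b -= 1
            if a <= b:
                regions.append((a + 1, b + 1, s[a : b + 1]))
            run = []
    return regions


def column_rule_oracle(n_q: int, n_gap: int, n_other: int) -> tuple[str, str]:
    """Direct transcription of the published column-classification rules."""
    n = n_q + n_gap + n_other
    frac = n_q / n
    if frac >= 0.8:
        return "conserved", "none"
    if frac < 0.2:
        return "uncategorized", "none"
    if n_gap > n_other:
        return "unstable", "inserted"
    if n_other > n_gap:
        return "unstable", "mutated"
    return "unstable", "undefined"


def region_rule_oracle(c: int, i: int, m: int, d: int) -> int:
    """Direct transcription of the five category definitions (1..5)."""
    u = i + m + d
    if c > u:
        return 1
    if u > c:
        if i > m and i > d:
            return 2
        if m > i and m > d:
            return 3
        return 4
    return 5


def random_protein(rng: random.Random, length: int, q_freq: float) -> str:
    return "".join(
        "Q" if rng.random() < q_freq else rng.choice(AA20.replace("Q", ""))
        for _ in range(length)
    )


def make_alignment(rows: dict[str, str] | list[str], set_id: str = "test") -> OrthologAlignment:
    """Build an alignment from {id: residues} or a bare list of row strings."""
    if isinstance(rows, list):
        rows = {f"r{i}": s for i, s in enumerate(rows)}
    return OrthologAlignment(
        set_id=set_id,
        rows=[SequenceRecord(id=k, residues=v) for k, v in rows.items()],
    )


@pytest.fixture
def alignment_factory():
    return make_alignment
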