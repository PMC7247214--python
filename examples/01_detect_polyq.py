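"""Detect polyQ regions in single protein sequences with the 4-in-6 rule.

A polyQ is any maximal span covered by windows of six residues holding at
least four glutamines, trimmed to terminal Q.  Impurities are allowed:
the human OFD1 tract QQEQDQ below has two non-Q residues yet qualifies.
"""

from polyq_evo import scan_polyq

sequences = {
    "OFD1-fragment": "MSTAV" + "QQEQDQ" + "LKRPE",
    "pure-tract": "AAAAQQQQQQQQAAAA",
    "two-tracts": "QQQQAAAAAAAAQQQQ",
    "dispersed-Q": "QAQAQAQAQAQA",  # never 4 Q in any 6-residue window
}

for name, seq in sequences.items():
    regions = scan_polyq(seq)
    print(f"{name}: {len(regions)} region(s)")
    for r in regions:
        print(f"  residues {r.start_res}-{r.end_res}: {r.sequence} ({r.n_q} Q)")

# Expected output: the OFD1 fragment yields one region, residues 6-11,
# sequence QQEQDQ; the pure tract one region of 8 Q; the third sequence
# two separate 4-Q regions; the dispersed sequence none.
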