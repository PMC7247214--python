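"""Categorize the evolutionary stability of a polyQ across orthologs.

Each region column is classified by the fraction of sequences carrying a
glutamine (conserved >= 80%, uncategorized < 20%, unstable in between,
with the unstable remainder split by gaps vs substitutions), and the
region takes the majority verdict: stable, inserted (length variation),
mutated (point substitution), undefined or uncategorized.
"""

from polyq_evo import OrthologAlignment, SequenceRecord, categorize_alignment

# ten orthologs: eight keep the tract, two lost it by deletion
rows = [SequenceRecord(id=f"sp{i}", residues="MAQQQQQAL") for i in range(8)]
rows += [SequenceRecord(id=f"sp{i}", residues="MA-----AL") for i in range(8, 10)]
aln = OrthologAlignment(set_id="demo", rows=rows)

for rc in categorize_alignment(aln):
    print(f"region columns {rc.region.col_start}-{rc.region.col_end}, "
          f"{rc.region.n_members} member(s) -> {rc.category.label}")
    for cc in rc.columns:
        print(f"  col {cc.col}: {cc.n_q}Q/{cc.n_gap}gap/{cc.n_other}other "
              f"-> {cc.value.value}/{cc.subvalue.value}")

# Every tract column has 8/10 = 80% glutamine, exactly the conserved
# boundary, so all five columns are conserved and the region is stable.
# Change two more rows to the gapped form and the columns drop to 60% Q
# with gaps dominating: the region becomes inserted.
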