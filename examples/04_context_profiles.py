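"""Amino-acid context around polyQ regions, per stability category.

One representative sequence (carrying the polyQ) is drawn per orthologous
region, and per-position residue frequencies are tallied at offsets
-10..-1 and +1..+10 from the region boundaries.  The generator's defaults
plant a leucine at -1 with probability 0.3 for stable regions (the
helix-promoting signal) and proline at 0.3 across +1..+10 for inserted
regions (the downstream capping signal).
"""

import numpy as np

import polyq_evo as pq
from polyq_evo.synthetic_data import SyntheticSpec

spec = SyntheticSpec()
rng = np.random.default_rng(1)

reps = {"stable": [], "inserted": []}
for category in reps:
    for i in range(300):
        aln, _, _ = pq.generate_ortholog_set(
            spec, category, rng, set_id=f"{category}{i}", with_cds=False
        )
        (rc,) = pq.categorize_alignment(aln)
        reps[category].append(pq.select_representative(rc.region, aln, rng))

for category in reps:
    for residue in "LP":
        prof = pq.residue_context_profile(reps[category], residue)
        print(f"{category:9s} {residue} at -1: {prof.freq(-1):.3f}   "
              f"+1: {prof.freq(1):.3f}   +5: {prof.freq(5):.3f}")

# Stable regions show L at -1 near the planted 0.3 while inserted regions
# stay at background (~0.05); the pattern flips for P downstream, which
# sits near 0.3 at +1..+10 only for inserted regions.
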