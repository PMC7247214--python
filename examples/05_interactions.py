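"""Interactor counts per protein from a STRING-style links table.

Only high-confidence partners (combined score strictly above 0.7; the
integer 0-1000 file scale is auto-detected) are counted.  Proteins
inherit the stability category of their set's polyQ region, and protein
length is compared alongside the counts as a confounder control.
"""

from pathlib import Path
import tempfile

import polyq_evo as pq

links_text = """\
protein1 protein2 combined_score
STB1 HUB1 0.92
STB1 HUB2 0.85
STB1 HUB3 0.71
STB1 HUB4 0.69
MUT1 HUB1 0.95
MUT1 HUB5 0.40
ORPHAN HUB9 0.99
"""

with tempfile.TemporaryDirectory() as tmp:
    links = Path(tmp) / "links.tsv"
    links.write_text(links_text)
    partners = pq.parse_links(links, threshold=0.7)

table = pq.attach_categories(
    partners,
    {"STB1": ["stable"], "MUT1": ["mutated"], "MISSING": ["stable"]},
    {"STB1": 420, "MUT1": 410, "MISSING": 300},
)
print(table.to_string(index=False))

# STB1 keeps 3 partners (0.69 fails the strict > 0.7 cut), MUT1 keeps 1,
# and MISSING is dropped: absent from the links table, we cannot tell "no
# interactors" from "not in the database".
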