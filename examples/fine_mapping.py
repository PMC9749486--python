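"""Delimiting a locus from recombinants and their progeny tests.

Three recombinant lines genotyped at seven fine markers (A = homozygous
early parent, B = homozygous late parent, H = heterozygous), plus two
less-informative lines.  Lines whose progeny segregate must be heterozygous
at the locus; fixed lines must be homozygous for the matching allele.
Intersecting those constraints pins the locus between two markers.
"""

import numpy as np
import pandas as pd

from bsaqtl import classify_progeny_segregation, delimit_interval
from bsaqtl.finemap import RecombinantLine

markers = [f"M{i}" for i in range(1, 8)]
marker_table = pd.DataFrame({"marker": markers,
                             "pos_bp": [29_700_000 + 43_000 * i
                                        for i in range(7)]})

# progeny phenotypes decide each line's status (early ~30 d, late ~38 d)
rng = np.random.default_rng(4)
progeny = {
    "R1": np.r_[rng.normal(30, 2, 11), rng.normal(38, 2, 9)],   # segregates
    "R2": rng.normal(38, 2, 18),                                # fixed late
    "R3": np.r_[rng.normal(30, 2, 10), rng.normal(38, 2, 10)],  # segregates
}
panel = {"R1": "AAAHBBB", "R2": "AAAABBB", "R3": "BBBHAAA",
         "N1": "AAABBBB", "N2": "AAAAAAB"}
statuses = {ln: classify_progeny_segregation(y, 30.0, 38.0)
            for ln, y in progeny.items()}
statuses.update({"N1": "fixed_late", "N2": "fixed_early"})

lines = [RecombinantLine(line=ln,
                         genotypes=pd.Series(list(codes), index=markers),
                         status=statuses[ln])
         for ln, codes in panel.items()]
for ln in panel:
    print(f"{ln}: {panel[ln]}  ->  {statuses[ln]}")

res = delimit_interval(lines, marker_table)
print(f"\nlocus delimited to ({res.left_marker}, {res.right_marker}): "
      f"{res.left_pos:,}-{res.right_pos:,} bp ({res.span_bp / 1000:.0f} kb)")
for ln, seg in res.constraints.items():
    print(f"  {ln} allows {seg[0]}..{seg[1]}")
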