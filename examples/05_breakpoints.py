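"""Call crossover breakpoints in a transmitted gamete.

A phased donor parent (heterozygous A/B at every marker, 2 cM spacing)
transmits a gamete with a prescribed crossover layout to a hybrid.  Markers
where the other parent is homozygous reveal the donor allele; matching those
alleles against the donor's two haplotypes decomposes the transmitted
chromosome into haplotype blocks, and each block transition is a crossover
breakpoint reported as the interval between its flanking markers.
"""

import numpy as np
import pandas as pd

from cpmap.haplotypes import PhasedLG, PhasedParent, donor_breakpoints
from cpmap.segcoding import observed_call
from cpmap.simdata import TrueLG, TrueMap, gamete_with_layout

rng = np.random.default_rng(4)
sizes = {"LG1": 120.0, "LG2": 90.0, "LG3": 100.0}
layout = {"LG1": 1, "LG3": 2}  # one crossover on LG1, two on LG3, none on LG2

lgs, rows = [], []
for lg_id, L in sizes.items():
    k = int(L // 2) + 1
    pos = np.linspace(0.0, L, k)
    names = [f"{lg_id}_{j:03d}" for j in range(k)]
    lgs.append(TrueLG(lg_id, names, pos))
    for nm, p in zip(names, pos):
        h = ("A", "B") if rng.random() < 0.5 else ("B", "A")
        rows.append({"marker": nm, "lg": lg_id, "pos": p, "marker_class": "snp",
                     "p1_h1": h[0], "p1_h2": h[1], "p2_h1": "A", "p2_h2": "A"})
info = pd.DataFrame(rows).set_index("marker")
truemap = TrueMap(lgs, info)

donor_gamete = gamete_with_layout(truemap, layout, rng)
phased, hybrid_calls, nondonor = {}, {}, {}
for lg in lgs:
    h1 = info.loc[lg.markers, "p1_h1"].tolist()
    h2 = info.loc[lg.markers, "p1_h2"].tolist()
    phased[lg.lg_id] = PhasedLG(lg.lg_id, lg.markers, lg.positions,
                                np.zeros(len(lg.markers), bool), h1, h2)
    org = donor_gamete.origins[lg.lg_id][0]
    for j, m in enumerate(lg.markers):
        donor_allele = h1[j] if org[j] == 0 else h2[j]
        hybrid_calls[m] = observed_call("A" + donor_allele)  # other parent gave A
        nondonor[m] = "AA"

report, dropped = donor_breakpoints(hybrid_calls, nondonor,
                                    PhasedParent("donor", phased), min_support=2)
print("breakpoints per linkage group:", report.counts(),
      "(layout was", {k: v for k, v in layout.items()}, ")")
for lg_id, blk in report.per_lg.items():
    for left, right, lo, hi in blk.breakpoints:
        true_pos = donor_gamete.crossovers[lg_id][0]
        print(f"  {lg_id}: crossover between {left} and {right} "
              f"({lo:.0f}-{hi:.0f} cM); true position(s) {np.round(true_pos, 1)}")
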