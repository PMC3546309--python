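"""Join two mapping datasets of one parent and compare maps across parents.

The same heterozygous parent is simulated in two crosses (as in a design
where it is the male parent of one progeny and the female parent of
another), with female meiosis recombining at 0.8x the male rate
(heterochiasmy).  Joining concatenates the gamete columns into one larger
dataset; remapping both datasets on their shared markers recovers the
length ratio, and the colinearity statistics confirm conserved marker order.
"""

import numpy as np

from cpmap import build_parent_map, code_markers, derive_gamete_matrix
from cpmap.mapcompare import colinearity_stats, common_marker_remap, join_parent_datasets
from cpmap.simdata import SimConfig, simulate_progeny
import pandas as pd

from cpmap.simdata import TrueLG, TrueMap

rng = np.random.default_rng(15)
lgs, rows = [], []
for i, L in enumerate([110.0, 90.0], start=1):
    pos = np.linspace(0.0, L, 14)
    names = [f"M{i}_{j + 1:02d}" for j in range(14)]
    lgs.append(TrueLG(f"LG{i}", names, pos))
    for nm, p in zip(names, pos):
        h = ("A", "B") if rng.random() < 0.5 else ("B", "A")
        rows.append({"marker": nm, "lg": f"LG{i}", "pos": p, "marker_class": "snp",
                     "p1_h1": h[0], "p1_h2": h[1], "p2_h1": "A", "p2_h2": "A"})
truemap = TrueMap(lgs, pd.DataFrame(rows).set_index("marker"))
anchor = truemap.marker_info["lg"].to_dict()

gm_male, _ = simulate_progeny(truemap, None, SimConfig(n_progeny=156), rng,
                              female_length_factor=1.0)
gm_female, _ = simulate_progeny(truemap, None, SimConfig(n_progeny=140), rng,
                                female_length_factor=0.8)
gam_m = derive_gamete_matrix(gm_male, code_markers(gm_male), 1, label="as_male")
gam_f = derive_gamete_matrix(gm_female, code_markers(gm_female), 1, label="as_female")

joined = join_parent_datasets(gam_m, gam_f, label="joined")
res = build_parent_map(joined, anchor_table=anchor)
print(f"joined dataset: {joined.n_progeny} gametes, "
      f"{res.genetic_map.total_markers} markers, "
      f"{res.genetic_map.total_length:.1f} cM reference map")

shared = [m for m in gam_m.markers if m in gam_f.markers]
maps, lengths = common_marker_remap({"male": gam_m, "female": gam_f}, shared,
                                    anchor_table=anchor)
print("\nper-LG lengths on the shared marker set (cM):")
print(lengths.round(1).to_string())
ratio = (lengths["female"] / lengths["male"]).mean()
print(f"female/male length ratio: {ratio:.2f} (simulated heterochiasmy: 0.80)")

col = colinearity_stats(maps["male"].genetic_map, maps["female"].genetic_map)
print("\ncolinearity (rank correlation of shared positions):")
print(col[["n_shared", "rho", "n_inversions"]].to_string())
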