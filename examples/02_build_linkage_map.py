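"""Estimate a linkage map from two-point recombination fractions: grouping
at a LOD threshold, seriation ordering, Kosambi distances."""

import numpy as np

from meiomap import CrossDesign, build_map, simulate_cross, uniform_true_map

tmap = uniform_true_map(n_lg=3, length_cM=100.0, spacing_cM=10.0)
n = len(tmap.markers)
cp = {"mother": np.vstack([np.zeros(n, np.int8), np.ones(n, np.int8)]),
      "father": np.zeros((2, n), np.int8)}
gm = simulate_cross(CrossDesign("CP", cp, 200, seed=5), tmap)

gmap = build_map(gm, lod_min=3.0, parent="mat", with_accessory=False)
print(f"{len(gmap.lgs())} linkage groups recovered "
      f"(simulated: {len(tmap.linkage_groups)})")
for lg in gmap.lgs():
    sub = gmap.table[gmap.table["lg"] == lg]
    print(f"  {lg}: {len(sub)} markers, {gmap.lg_length(lg):.1f} cM")
print("Each group's span is a sum of adjacent Kosambi distances; at 200 "
      "offspring the simulated 100 cM groups are recovered to within a few "
      "cM and the marker order matches the simulation (up to reversal).")
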