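"""Compare recombination rates between two genotypes whose maps share a
marker panel: paired Wilcoxon over all within-group pairwise recombination
fractions, then per-pair Z-tests."""

import numpy as np
import pandas as pd

from meiomap import CrossDesign, build_paired_rf, simulate_cross, uniform_true_map, wilcoxon_paired, ztest_rf
from meiomap.simulate import TrueMap

# genotype A recombines 1.2x faster everywhere (12 chromosomes x ~1 Morgan)
tmap_b = uniform_true_map(12, 98.0, 14.0)
mod = {"mother": {lg: [(0.0, Lg, 1.2)] for lg, Lg in tmap_b.linkage_groups}}
tmap_a = TrueMap(tmap_b.linkage_groups, tmap_b.markers, mod)
n = len(tmap_b.markers)
cp = {"mother": np.vstack([np.zeros(n, np.int8), np.ones(n, np.int8)]),
      "father": np.zeros((2, n), np.int8)}
gm_a = simulate_cross(CrossDesign("CP", cp, 69, seed=4), tmap_a)
gm_b = simulate_cross(CrossDesign("CP", cp, 83, seed=5), tmap_b)

common = pd.DataFrame({"marker": tmap_b.markers["marker"],
                       "lg": tmap_b.markers["lg"]})
paired = build_paired_rf(gm_a, gm_b, common)
v, p = wilcoxon_paired(paired["rf_a"], paired["rf_b"])
print(f"{len(paired)} aligned marker pairs; paired Wilcoxon p = {p:.2e}")
print(f"median rf difference (A - B) = "
      f"{np.median(paired['rf_a'] - paired['rf_b']):.4f}")

n1, n2 = paired["n_a"].mean(), paired["n_b"].mean()
sig = [(r["pair"], ztest_rf(min(r['rf_a'], .5), min(r['rf_b'], .5), n1, n2))
       for _, r in paired.iterrows()]
pos = sum(1 for _m, z in sig if z.p_value < 0.05 and z.z > 0)
neg = sum(1 for _m, z in sig if z.p_value < 0.05 and z.z < 0)
print(f"significant Z-tests (P<0.05): {pos} with A>B vs {neg} with A<B")
print("The genome-wide excess of positive differences shows genotype A "
      "recombines more; individual pairs are rarely significant alone "
      "because each family contributes only ~70-80 meioses.")
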