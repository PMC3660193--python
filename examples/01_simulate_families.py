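"""Simulate the two mapping designs: an outbred full-sib family (CP) and a
selfed F2, from the same ground-truth genome, and write genotype TSVs."""

import numpy as np

from meiomap import CrossDesign, ViabilityLocus, simulate_cross, uniform_true_map, write_genotypes

# 3 chromosomes x 100 cM, a marker every 5 cM; a recessive sublethal
# viability locus sits at 50 cM on LG2 (fitness of one homozygote = 0.2)
tmap = uniform_true_map(
    n_lg=3, length_cM=100.0, spacing_cM=5.0,
    viability_locus=ViabilityLocus("LG2", 50.0, {"BB": 0.2}))
n = len(tmap.markers)

# selfed F1 hybrid: haplotype 0 = one grandparent, haplotype 1 = the other
f1 = {"H12": np.vstack([np.zeros(n, np.int8), np.ones(n, np.int8)])}
gm_f2 = simulate_cross(CrossDesign("F2_SELF", f1, 69, seed=1), tmap,
                       error_rate=0.002, missing_rate=0.02)

# outbred cross: mother het everywhere, father homozygous -> 1:1 maternal loci
cp = {"mother": np.vstack([np.zeros(n, np.int8), np.ones(n, np.int8)]),
      "father": np.zeros((2, n), np.int8)}
gm_cp = simulate_cross(CrossDesign("CP", cp, 83, seed=2), tmap)

for gm, path in ((gm_f2, "f2_genotypes.tsv"), (gm_cp, "cp_genotypes.tsv")):
    write_genotypes(gm, path)
    print(f"{path}: {gm.population_type} population, "
          f"{len(gm.calls)} markers x {gm.n_offspring} offspring")

c = gm_f2.counts("LG2_m010")  # the marker at the viability locus
print(f"genotype counts at the viability locus: {c}")
print("The BB class (homozygous for the sublethal allele) falls well below "
      "the 1:2:1 expectation because most BB zygotes died.")
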