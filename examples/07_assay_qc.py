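"""SNP-assay bookkeeping: conversion and poor-performance rates, and the
same-contig genotyping-error check."""

from meiomap import CrossDesign, contig_consistency, qc_summary, simulate_cross, uniform_true_map
import numpy as np

qc = qc_summary(n_polymorphic=2264, n_poor=2156, n_total=9279)
print(f"conversion rate: {qc.conversion_rate}%  "
      f"(polymorphic {qc.n_polymorphic} of {qc.n_total_assayed} assayed)")
print(f"poorly performing: {qc.poor_rate}%; monomorphic: {qc.n_monomorphic}")

# same-contig check: markers from one contig are ~0 recombination apart, so
# any call disagreement between them within an individual is a typing error
tmap = uniform_true_map(1, 50.0, 10.0, contig_copies=2)
f1 = {"F1": np.vstack([np.zeros(len(tmap.markers), np.int8),
                       np.ones(len(tmap.markers), np.int8)])}
gm = simulate_cross(CrossDesign("F2_SELF", f1, 200, seed=6), tmap,
                    error_rate=0.002)
n_comp, n_evt, rate = contig_consistency(gm)
print(f"same-contig comparisons: {n_comp}, discordances: {n_evt}, "
      f"error rate: {rate:.2f}%")
print("With a 0.2% simulated typing error, pairs of same-contig markers "
      "disagree at roughly twice that rate (either copy can be wrong).")
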