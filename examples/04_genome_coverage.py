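"""Genome length and map coverage: observed length, the Chakravarti
method-4 expected length, observed coverage, and the Bishop expected
coverage for a given maximum marker gap."""

from meiomap import (
    expected_coverage_bishop, expected_length_chakravarti, marker_density,
    observed_coverage, observed_length,
)

# per-linkage-group spans (cM) and framework marker counts of a dense map
lg_lengths = [138, 125, 121, 150, 145, 115, 128, 183, 130, 140, 166, 167]
lg_markers = [95, 90, 88, 102, 96, 69, 92, 122, 90, 94, 96, 87]

G0 = observed_length(lg_lengths, gap_adjust_cM=0.0)
Ge = expected_length_chakravarti(lg_lengths, lg_markers)
Co = observed_coverage(G0, Ge)
Ce = expected_coverage_bishop(R=12, N=sum(lg_markers), X=30.0, Ge=Ge)

print(f"observed genome length G0 = {G0:.0f} cM")
print(f"expected genome length Ge = {Ge:.0f} cM  (Chakravarti method 4)")
print(f"observed coverage Co = {Co:.0f}%")
print(f"expected coverage Ce = {Ce:.4f}  (Bishop, X = 30 cM)")
print(f"marker density = {marker_density(G0, sum(lg_markers))} cM/locus")
print("Ge corrects each group's span for chromosome ends beyond the terminal "
      "markers; Ce near 1 means a random gene almost surely lies within "
      "X cM of some mapped marker - a saturated map.")
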