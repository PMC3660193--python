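# Methods

This note documents the models, statistics and design choices behind
`meiomap`, in the order the pipeline applies them.

## Meiosis model and the synthetic families

Gametes are simulated per linkage group as a Poisson count–location
process: the number of crossovers on a gamete is Poisson with mean equal to
the group's length in Morgans, and crossover locations are i.i.d. uniform.
This is the no-interference (Haldane) model; an interference-free process
was chosen because every closed-form oracle used in the tests (the Haldane
map function, the testcross likelihood) is exact under it. Chiasma
interference is deliberately not simulated — none of the downstream
statistics condition on it — and the small systematic difference this
creates against Kosambi-scale distances is handled by testing recombination
fractions, not cM, against truth (see "Numerical choices").

Local recombination-rate variation is expressed as a per-parent,
piecewise-constant multiplier track over cM intervals (1.0 = baseline).
Counts and locations are drawn on the *warped* scale obtained by
integrating the track, then mapped back to physical cM, so a ×2 interval
recombines exactly like an interval twice as long (verified against the
Haldane closed form in the tests).

Two mating designs are supported:

* **CP (two-way pseudo-testcross)** — two unrelated, phased parents. Loci
  heterozygous in one parent segregate 1:1 and are informative for that
  parent's meioses only; loci heterozygous in both segregate 1:2:1.
* **F2_SELF** — a selfed F1 hybrid whose two haplotypes descend from two
  known grandparents; every heterozygous locus segregates 1:2:1, and
  grandparental origin is meaningful for each offspring haplotype.

An optional **viability locus** removes zygotes after fertilisation:
survival probability equals the fitness of the zygote's genotype class at
the locus, classes keyed by the number of haplotype-1 alleles ("AA", "AB",
"BB", each fitness in [0, 1], at least one class at 1.0). Sampling rejects
until the requested number of survivors is reached, so the delivered family
is the post-selection one. Genotyping noise is applied last: with
probability `error_rate` a call is replaced by a random *different legal*
code for that marker's segregation type (a symmetric substitution model —
the simplest model consistent with the sub-percent discordance rates seen
on SNP arrays), and with probability `missing_rate` it is masked.

Defaults used by the demo pipeline mirror a typical SNP-array mapping
study in a conifer: 83 outbred and 69 selfed offspring, a 380-offspring
validation cohort, α = 0.01, genotyping error 0.2 %, missingness 2 %. The
selection coefficient of the planted sublethal allele is a free parameter
(the studies use s = 0.8 for the demo and s = 1 for power analyses), since
the real-world value is not identified by the published data.

What the generator does **not** emulate: crossover interference, sex
differences in recombination beyond what the user encodes in modifier
tracks, segregation of more than two alleles per locus, linkage-dependent
genotyping artefacts (e.g. cluster compression on arrays), and any
sequence-level process. Tests passing on these simulations therefore
establish the statistical machinery, not array-chemistry robustness.

All randomness flows from one integer seed; per-stage streams are derived
with `numpy.random.SeedSequence`, and identical configurations reproduce
outputs byte-for-byte.

## Two-point estimation and map construction

For two 1:1 (testcross) markers of the same parent, the recombination
fraction is the minority class frequency over pairwise-complete
individuals, θ̂ = min(m, n−m)/n (phase unknown), and the support is the
base-10 likelihood ratio LOD = n log₁₀2 + R log₁₀θ̂ + (n−R) log₁₀(1−θ̂),
with the 0·log 0 = 0 convention at the boundaries, so LOD(θ̂=0) = n log₁₀2
and LOD(θ̂=0.5) = 0. For two codominant 1:2:1 markers, θ̂ maximises the F2
likelihood of the 3×3 genotype table by EM (the double-heterozygote cell is
the only one with a latent recombinant count); both phases are fitted and
the higher-likelihood phase kept. Tests verify EM against a dense grid
search of an independently coded likelihood. Mixed testcross × intercross
pairs (used for accessory placement) are reduced to an exact testcross
problem by dropping the uninformative heterozygous calls of the intercross
marker.

Distances are Kosambi, d = ¼ ln((1+2θ)/(1−2θ)) Morgans, inverse
θ = ½ tanh(2d); the round trip is exact to 10⁻¹⁰ over θ ∈ [0, 0.49].

Grouping is the transitive closure of pairs with LOD ≥ threshold (default
3, the conventional mapping threshold). **Caveat**: with hundreds of
markers the number of inter-group pairs is 10⁴–10⁵, and the phase-folded
estimator doubles the lower tail of θ̂ under independence, so at n ≈ 70–80
meioses LOD 3 admits spurious links that merge true groups. The replicated
studies therefore group 12-group genomes at LOD 5 (≈ log₁₀ #pairs plus
margin), which recovered 12/12 groups in every development replicate. This
mirrors the stepwise-LOD practice of interactive mapping software.

Ordering within a group is greedy nearest-neighbour seriation (best of all
starts) refined by 2-opt on the summed adjacent recombination fractions —
a transparent heuristic whose acceptance criterion is truth recovery on
simulations (exact order recovery at ≥ 2 cM spacing with 500 offspring),
not concordance with any multipoint package. Output orientation is
canonical (lexicographically smaller terminal marker first), making the
result invariant to input order up to that convention. Positions accumulate
Kosambi distances between adjacent markers. Markers with less linkage
information (1:2:1 loci in a CP design) are attached as *accessory*
markers to the framework position with maximal two-point LOD, ties broken
by smaller distance; unlinked markers are reported unplaced.

The same-contig consistency check estimates the genotyping error rate:
markers from one contig are effectively zero recombination apart, so after
re-orienting allele coding (the labelling of A/B is arbitrary per marker),
any within-individual disagreement between same-contig markers counts as
one typing error over one comparison.

## Segregation distortion and the inbred/outbred contrast

Each marker is tested against its Mendelian ratio (1:1 or 1:2:1) with a
Pearson chi-square; `distorted` means p ≤ α (default 0.01). No continuity
correction and no multiple-testing adjustment are applied — this is the
classical per-marker convention, and users should remember that ~1 % of
markers are flagged by chance at α = 0.01; the clustering step exists
precisely to separate chance flags from genetic signal. A warning (not an
error) is attached when any expected class count is below 5.

A **segregation distortion region (SDR)** is a maximal run of ≥
`min_cluster` (default 3) distorted markers along a group, where untested
markers do not break the run but a tested non-distorted marker does, and
consecutive distorted members must lie within `max_gap_cM` (default 10).
Shorter runs are reported as singletons. The defaults are an
operationalisation: 3 is the shortest run clearly distinguishable from
isolated α = 0.01 false positives, and both are exposed as parameters.

The biological logic of the contrast: an SDR in the selfed progeny whose
interval — projected onto each outbred parental map through shared anchor
markers (piecewise-linear interpolation, constant extrapolation beyond the
terminal anchors) — contains no distorted marker on either parental map
indicates a recessive deleterious allele revealed by inbreeding, rather
than gametic selection. Candidates are then re-tested in an independent,
larger cohort; a region is *validated* when at least `min_cluster` member
markers remain distorted there. Distortion confined to one parental
(gametic) map is classified *prezygotic*; distortion in zygotic ratios (or
on both parental maps) *postzygotic*; otherwise *undetermined*. Finally,
the grandparental origin of the deficient allele is read off the selfed
parent's phase: the homozygote class significantly below its ¼ expectation
names the grandparent whose haplotype it carries.

## Genome length and coverage

Observed length G0 is the summed group span plus an explicit gap adjustment
for known split groups. Expected length applies the Chakravarti method-4
correction per group, Ge = Σ lᵢ(mᵢ+1)/(mᵢ−1) over framework markers, which
assumes uniform marker placement. Observed coverage Co = 100·G0/Ge.
Expected coverage uses the Bishop random-marker model

    Ce = 1 − [ (2R/(N+1)) ((1−X/(2Ge))^(N+1) − (1−X/Ge)^(N+1))
               + (1 − RX/Ge)(1−X/Ge)^N ],

clamped to [0, 1], with R the haploid chromosome number, N the framework
locus count and X the maximum accepted adjacent gap in cM. **The printed
rendering of this expression in the source literature is typographically
corrupted**; the form above is the reconstruction whose terms match the
printed fragments and whose limits behave correctly (X = 0 → Ce = 0;
N → ∞ → Ce → 1, both asserted in tests, plus monotonicity in X and N over
a numeric grid). Because the published analyses do not state which LOD
level's maximum gap was used for X, X is a required explicit input here.
Marker density (cM/locus) divides G0 by *all* mapped markers (framework +
accessory), the denominator that reconciles the published density figures;
Ge uses framework counts only.

## Recombination landscape

Marker density along a saturated gene-based map is inversely related to
local recombination rate. Per linkage group, a Gaussian-kernel bandwidth h
is chosen by a two-stage direct-plug-in (Sheather–Jones-type) rule,
implemented from the Hermite-polynomial functional estimates (no SciPy
implementation exists); it agrees with R's `bw.SJ(method="dpi")` to ~0.1 %
on a frozen fixture and falls back to Silverman's rule with a 1 cM floor
below 5 markers or for degenerate spreads. Windows [x, x+h) slide in 1-cM
steps from position 0; the final partial window is dropped so all windows
share one width and a common Poisson rate.

Thresholds are fitted on the pooled window counts of the whole map (per
the small-expected-count argument for pooling): λ is the mean count, and
the coldspot threshold k_cold is the smallest k > λ at which the observed
number of windows with count ≥ k exceeds the Poisson expectation *and*
that pooled tail is significant; symmetrically k_hot for counts ≤ k.
Significance uses the **exact binomial tail probability** (tail windows ~
Binomial(n_windows, Poisson tail probability)), Bonferroni-divided by the
number of scanned k per tail. A one-cell chi-square was considered and
rejected: with expected tail counts far below one it is strongly
anti-conservative (≈14 % null firing at 300 windows in development
measurements), whereas the exact Bonferroni scan fires on homogeneous maps
at ≈0.5 % at α = 0.01 while leaving planted-signal detection untouched
(their tail p-values are many orders of magnitude below any threshold).
The chi-square is still reported in the per-k table for reference.

Qualifying consecutive windows merge into intervals
[first start, last start + h). Intervals are matched across maps by
projecting spans through shared anchors (overlap = match); Venn counts
(specific / shared-by-two / shared-by-all) come from connected components
of the match graph, and pairwise similarity is the Jaccard index
|matched| / |union|. One caveat, visible in the examples: because
bandwidths are per-group but thresholds are map-wide, a group whose
overall density departs from the map average can be flagged wholesale;
whole-group calls deserve scepticism.

## Comparing recombination between genotypes

Rates are compared only at markers shared by both maps and free of
segregation distortion (distortion biases θ̂). The genome-wide test is a
paired Wilcoxon signed-rank over all within-group pairwise recombination
fractions (or over group lengths for a whole-map test): zeros dropped,
ties mid-ranked, exact null distribution below 20 informative pairs when
ranks are untied, otherwise the normal approximation with continuity
correction (verified against full 2⁸ sign enumeration). Per-pair
follow-up uses the two-proportion Z-test

    Z = (θ₁ − θ₂) / √(θ₁(1−θ₁)/n₁ + θ₂(1−θ₂)/n₂),

where n₁, n₂ are the *mean* informative-meiosis counts per map (per-pair
counts are available as an option). No multiplicity correction is applied
across pairs, matching the convention of highlighting significant pairs;
the Wilcoxon carries the inferential weight. Note that all pairs of one
map share the same meioses, so pairwise values are strongly correlated:
a genome-wide ratio of ~1.2 is intrinsically a ~2σ effect on a 3-Morgan
genome at these family sizes and only becomes decisively detectable on a
12-chromosome (~12 Morgan) genome — which is why the replicated studies
use 12 groups.

One calibration caveat, measured during development and worth stating
plainly: the per-pair Z-test is null-calibrated (empirical rejection ≈ the
nominal rate), but the genome-wide Wilcoxon over pairwise recombination
fractions is **anti-conservative under the null** — in simulations with
identical landscapes, ~40 % of replicates gave p < 0.05 — because every
pair of one map is computed from the same meioses, violating the
signed-rank independence assumption. Planted-effect detection remains
meaningful (a genuine 1.2× ratio yields p many orders of magnitude smaller
than the null distribution produces), but the printed p-value overstates
the evidence and should be read qualitatively. The Wilcoxon over the 12
*group lengths* is much closer to calibrated, as groups are nearly
independent.

Marker distribution across groups is tested by Pearson chi-square with
expected counts proportional to group length, and cross-map collinearity
is summarised as group-assignment discordances plus rank-order inversions
(after orienting each group for agreement; a whole-group reversal is not a
discordance), with a Spearman correlation per group.

## Problem sizes in the replicated studies

The studies behind `tests/test_acceptance.py` and `scripts/acceptance.py`
use: 100 replicates (50 in the script) of the full SDR pipeline at
discovery n = 69, outbred n = 83, validation n = 380 on a 2×100 cM genome
with 5 cM marker spacing; planted ×3 hot/coldspots on a 3×120 cM genome at
1 cM spacing with 500 offspring (5 replicates; the coldspot's true region
is 60 cM wide because map-scale compression divides its footprint by the
effect size); a 12×98 cM genome at 14 cM spacing for the 1.2× rate-ratio
study (336 pairs, n = 69 vs 83); and 20/12 replicates of n = 10,000
two-point estimates at θ ∈ {0.05, 0.1, 0.2, 0.3} so the Monte-Carlo error
(~0.001) sits well below the 0.005 bias criterion. SDR clustering in these
studies runs on the known simulated coordinates — mapping fidelity is
established separately by the order-recovery study — which isolates the
distortion statistics from ordering noise.

## Known limitations

* No interference model is exposed beyond the modifier tracks; organisms
  with strong positive interference will show narrower crossover-count
  dispersion than simulated.
* The ordering heuristic is O(n²)–O(n³) per group and aimed at hundreds,
  not tens of thousands, of markers.
* Per-marker chi-squares are reported unadjusted; genome-wide error is
  controlled only through the clustering/validation design.
* The landscape caller inherits the per-group-bandwidth / map-wide-threshold
  asymmetry discussed above.
* Map comparison assumes shared marker names identify shared loci;
  paralogy is only surfaced indirectly through collinearity discordances.
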