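"""Genome length and map-coverage estimation.

Observed genome length G0 is the summed span of the linkage groups, plus an
optional fixed adjustment for a known gap (e.g. a linkage group split into
two subgroups).  Expected genome length Ge applies the Chakravarti et al.
method-4 correction per linkage group, Ge = sum_i length_i * (m_i+1)/(m_i-1)
with m_i framework markers on group i, which assumes marker locations are
uniform on each group.  Observed coverage Co = G0/Ge.  Expected coverage Ce
follows the Bishop et al. random-marker model for the probability that a
random genome point lies within X cM of a mapped locus:

    Ce = 1 - [ (2R/(N+1)) * ((1-X/(2Ge))^(N+1) - (1-X/Ge)^(N+1))
               + (1 - R*X/Ge) * (1-X/Ge)^N ]

with R the haploid chromosome number, N the framework locus count and X the
maximum accepted adjacent-marker gap in cM.  The published rendering of this
expression is typographically corrupted in the source literature as printed;
the form above is the reconstruction whose terms match the printed fragments
and whose limits behave correctly (X=0 -> Ce=0; N -> infinity -> Ce -> 1).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CoverageStats",
    "observed_length",
    "expected_length_chakravarti",
    "observed_coverage",
    "expected_coverage_bishop",
    "marker_density",
    "coverage_stats",
]


@dataclass(frozen=True)
class CoverageStats:
    G0: float  # observed genome length, cM (incl. gap adjustment)
    Ge: float  # expected genome length, cM
    Co: float  # observed coverage, percent
    Ce: float  # expected coverage, fraction in [0, 1]
    R: int  # haploid chromosome number
    N: int  # framework marker count
    X: float  # max accepted adjacent gap, cM
    density_cM_per_locus: float


def observed_length(lg_lengths, gap_adjust_cM: float = 0.0) -> float:
    """Sum of linkage-group spans plus a fixed gap adjustment (cM >= 0)."""
    if gap_adjust_cM < 0:
        raise ValueError("gap adjustment must be non-negative")
    return float(sum(lg_lengths)) + gap_adjust_cM


def expected_length_chakravarti(lg_lengths, framework_counts) -> float:
    """Ge = sum_i length_i * (m_i + 1)/(m_i - 1); every m_i must be >= 2."""
    lengths = list(lg_lengths)
    counts = list(framework_counts)
    if len(lengths) != len(counts):
        raise ValueError("one framework-marker count needed per linkage group")
    ge = 0.0
    for L, m in zip(lengths, counts):
        if m < 2:
            raise ValueError("each linkage group needs at least 2 markers")
        ge += L * (m + 1) / (m - 1)
    return ge


def observed_coverage(G0: float, Ge: float) -> float:
    """Observed coverage 100*G0/Ge (percent, unrounded)."""
    if Ge <= 0:
        raise ValueError("Ge must be positive")
    return 100.0 * G0 / Ge


def expected_coverage_bishop(R: int, N: int, X: float, Ge: float) -> float:
    """Bishop et al. expected map coverage, clamped to [0, 1]."""
    if not 0 <= X <= Ge:
        raise ValueError("X must lie in [0, Ge]")
    if N < 1 or R < 1:
        raise ValueError("N and R must be >= 1")
    term = (2.0 * R / (N + 1)) * ((1 - X / (2 * Ge)) ** (N + 1)
                                  - (1 - X / Ge) ** (N + 1))
    term += (1 - R * X / Ge) * (1 - X / Ge) ** N
    return min(1.0, max(0.0, 1.0 - term))


def marker_density(G0: float, n_mapped: int) -> float:
    """Mean map distance per mapped locus, cM, one decimal."""
    if n_mapped < 1:
        raise ValueError("n_mapped must be >= 1")
    return round(G0 / n_mapped, 1)


def coverage_stats(genetic_map, R: int, X: float, gap_adjust_cM: float = 0.0,
                   n_mapped: int | None = None) -> CoverageStats:
    """All coverage statistics for one :class:`~meiomap.twopoint.GeneticMap`."""
    lengths = genetic_map.lg_lengths()
    counts = genetic_map.framework_counts()
    lgs = list(lengths)
    G0 = observed_length([lengths[g] for g in lgs], gap_adjust_cM)
    Ge = expected_length_chakravarti([lengths[g] for g in lgs],
                                     [counts[g] for g in lgs])
    N = int(sum(counts.values()))
    if n_mapped is None:
        n_mapped = len(genetic_map.table)
    return CoverageStats(
        G0=G0, Ge=Ge, Co=observed_coverage(G0, Ge),
        Ce=expected_coverage_bishop(R, N, X, Ge),
        R=R, N=N, X=X, density_cM_per_locus=marker_density(G0, n_mapped),
    )
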