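"""Statistical comparison of recombination rates and marker distribution.

Recombination rates are compared between the maps of different genotypes in
two stages, using only markers common to both maps and free of segregation
distortion (distortion biases recombination-fraction estimates): first a
paired Wilcoxon signed-rank test over the within-linkage-group pairwise
recombination fractions (or over linkage-group lengths for a whole-map sex or
genetic-background test), then per-pair two-proportion Z-tests

    Z = (theta1 - theta2) / sqrt(theta1(1-theta1)/n1 + theta2(1-theta2)/n2)

with n1, n2 the mean numbers of informative meioses per map.  Marker
distribution across linkage groups is tested with a Pearson chi-square where
the expected count per group is proportional to its map length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .twopoint import rf_f2, rf_testcross

__all__ = [
    "ZTestResult",
    "wilcoxon_paired",
    "ztest_rf",
    "build_paired_rf",
    "chi2_marker_distribution",
    "collinearity_check",
]


@dataclass(frozen=True)
class ZTestResult:
    theta1: float
    theta2: float
    n1: float
    n2: float
    z: float
    p_value: float


def wilcoxon_paired(values_a, values_b):
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties are mid-ranked.  The exact null
    distribution is used below 20 informative pairs when there are no tied
    ranks, otherwise the normal approximation with continuity correction.
    Returns ``(V, p)``; all-zero differences give (0, 1.0) with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        import warnings

        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    exact_ok = len(d) < 20 and len(np.unique(np.abs(d))) == len(d)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         method="exact" if exact_ok else "approx")
    return float(res.statistic), float(res.pvalue)


def ztest_rf(theta1: float, theta2: float, n1: float, n2: float) -> ZTestResult:
    """Two-proportion Z-test on recombination fractions of a marker pair."""
    for th in (theta1, theta2):
        if not 0.0 <= th <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")
    var = theta1 * (1 - theta1) / n1 + theta2 * (1 - theta2) / n2
    if var <= 0:
        raise ValueError("both theta are 0: Z undefined (zero variance)")
    z = (theta1 - theta2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(theta1, theta2, n1, n2, float(z), float(p))


def _rf_one(gm, ma: str, mb: str):
    st = gm.markers.loc[ma, "seg_type"]
    fn = rf_f2 if st == "1:2:1" else rf_testcross
    return fn(gm.calls.loc[ma], gm.calls.loc[mb], ma, mb)


def build_paired_rf(gm_a, gm_b, common_markers: pd.DataFrame,
                    exclude: set[str] | None = None) -> pd.DataFrame:
    """Aligned within-LG pairwise recombination fractions on two maps.

    ``common_markers``: DataFrame (marker, lg) of loci genotyped in both
    populations; ``exclude`` removes distorted loci.  Returns columns
    pair, lg, rf_a, rf_b, n_a, n_b.
    """
    mk = common_markers
    if exclude:
        mk = mk[~mk["marker"].isin(exclude)]
    rows = []
    for lg, sub in mk.groupby("lg"):
        ids = [m for m in sub["marker"]
               if m in gm_a.calls.index and m in gm_b.calls.index]
        if len(ids) < 2:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ma, mb = ids[i], ids[j]
                # a pair is only estimable when both markers share a
                # segregation type within each population
                if (gm_a.markers.loc[ma, "seg_type"] != gm_a.markers.loc[mb, "seg_type"]
                        or gm_b.markers.loc[ma, "seg_type"] != gm_b.markers.loc[mb, "seg_type"]):
                    continue
                try:
                    la = _rf_one(gm_a, ma, mb)
                    lb = _rf_one(gm_b, ma, mb)
                except ValueError:
                    continue
                rows.append((f"{ma}--{mb}", lg, la.rf, lb.rf,
                             la.n_informative, lb.n_informative))
    if not rows:
        raise ValueError("no common marker pairs between the two maps")
    return pd.DataFrame(rows, columns=["pair", "lg", "rf_a", "rf_b", "n_a", "n_b"])


def chi2_marker_distribution(lg_lengths, lg_counts):
    """Chi-square of marker counts across LGs vs length-proportional
    expectation; returns (chi2, df, p)."""
    L = np.asarray(lg_lengths, dtype=float)
    O = np.asarray(lg_counts, dtype=float)
    if len(L) < 2:
        raise ValueError("need at least 2 linkage groups")
    if (L <= 0).any():
        raise ValueError("zero-length linkage group")
    E = L / L.sum() * O.sum()
    chi2, p = stats.chisquare(O, E)
    return float(chi2), len(L) - 1, float(p)


def collinearity_check(map_a, map_b) -> dict:
    """Cross-map discordance report for shared markers.

    Lists markers assigned to different linkage groups, counts within-LG
    rank-order inversions (marker pairs whose order flips between maps,
    after orienting each LG for maximal agreement), and reports a Spearman
    rank correlation per LG.
    """
    ta = map_a.table.set_index("marker")
    tb = map_b.table.set_index("marker")
    shared = [m for m in ta.index if m in tb.index]
    if not shared:
        raise ValueError("no common markers between maps")
    lg_mismatch = [m for m in shared if ta.loc[m, "lg"] != tb.loc[m, "lg"]]
    same = [m for m in shared if m not in set(lg_mismatch)]
    inversions = []
    rank_corr = {}
    sub = pd.DataFrame({
        "lg": [ta.loc[m, "lg"] for m in same],
        "pos_a": [ta.loc[m, "position"] for m in same],
        "pos_b": [tb.loc[m, "position"] for m in same],
    }, index=same)
    for lg, grp in sub.groupby("lg"):
        if len(grp) < 2:
            continue
        rho = stats.spearmanr(grp["pos_a"], grp["pos_b"]).statistic
        if rho < 0:  # whole-LG reversal between the maps, not a discordance
            grp = grp.assign(pos_b=-grp["pos_b"])
            rho = -rho
        rank_corr[lg] = float(rho)
        ms = list(grp.index)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                da = grp.loc[ms[i], "pos_a"] - grp.loc[ms[j], "pos_a"]
                db = grp.loc[ms[i], "pos_b"] - grp.loc[ms[j], "pos_b"]
                if da * db < 0:
                    inversions.append((lg, ms[i], ms[j]))
    return {
        "lg_assignment_discordances": lg_mismatch,
        "order_discordances": inversions,
        "rank_correlation": rank_corr,
        "n_discordances": len(lg_mismatch) + len(inversions),
    }
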