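"""Segregation-distortion tests, SDR detection and the inbred/outbred contrast.

Each marker is tested for goodness of fit to its expected Mendelian ratio
(1:1 for testcross markers, 1:2:1 for intercross/F2 markers) with a Pearson
chi-square; a marker is "distorted" at P <= alpha (default 0.01).  No
continuity correction and no multiple-testing adjustment are applied — the
per-marker raw-P convention of classical linkage-mapping QC; the docs note
the multiplicity caveat.

Distorted markers that cluster along a linkage group form a segregation
distortion region (SDR).  The biological logic of the inbred/outbred
contrast: an SDR present in the selfed-F2 progeny but absent from both
parental maps of the outbred family points to a (semi-)lethal recessive
revealed by inbreeding; distortion restricted to one parental map points to
gametic (prezygotic) selection instead.  Candidate SDRs from a small
discovery cohort are re-tested in a larger validation cohort, and the
grandparental origin of the deficient allele is read off the F1 phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegTestResult",
    "SDRegion",
    "chi2_ratio_test",
    "test_matrix",
    "detect_sdr",
    "contrast_pedigrees",
    "validate_sdr",
    "classify_stage",
    "transmission_origin",
]

RATIOS = {"1:1": (1, 1), "1:2:1": (1, 2, 1)}


@dataclass(frozen=True)
class SegTestResult:
    marker: str
    counts: tuple[int, ...]
    ratio: tuple[int, ...]
    chi2: float
    df: int
    p_value: float
    distorted: bool
    low_expected: bool = False  # any expected class count < 5


@dataclass
class SDRegion:
    lg: str
    start: float
    end: float
    members: list[str]
    n_distorted: int
    origin_map: str = ""
    status: str = "candidate"  # candidate | validated | rejected
    stage: str = "undetermined"  # prezygotic | postzygotic | undetermined
    deficient_origin: str | None = None

    def contains(self, position: float, slack: float = 0.0) -> bool:
        return self.start - slack <= position <= self.end + slack


def chi2_ratio_test(counts, ratio="1:2:1", alpha: float = 0.01,
                    marker: str = "m") -> SegTestResult:
    """Pearson chi-square of observed genotype-class counts against a
    Mendelian ratio; ``distorted`` iff p <= alpha."""
    counts = tuple(int(c) for c in counts)
    ratio_t = RATIOS[ratio] if isinstance(ratio, str) else tuple(ratio)
    if len(counts) != len(ratio_t):
        raise ValueError("ratio does not match the number of genotype classes")
    total = sum(counts)
    if total == 0:
        raise ValueError("zero total count")
    expected = np.array(ratio_t, dtype=float) / sum(ratio_t) * total
    chi2, p = stats.chisquare(np.array(counts, dtype=float), expected)
    return SegTestResult(
        marker, counts, ratio_t, float(chi2), len(counts) - 1, float(p),
        bool(p <= alpha), bool((expected < 5).any()),
    )


def test_matrix(gm, alpha: float = 0.01) -> dict[str, SegTestResult]:
    """Per-marker segregation tests for a whole genotype matrix.

    1:1 markers use the two observed classes; 1:2:1 markers use (A, H, B).
    Uninformative markers are skipped.  Missing calls are excluded.
    """
    out: dict[str, SegTestResult] = {}
    for m in gm.calls.index:
        st = gm.markers.loc[m, "seg_type"]
        c = gm.counts(m)
        if st == "1:2:1":
            out[m] = chi2_ratio_test((c["A"], c["H"], c["B"]), "1:2:1", alpha, m)
        elif st in ("1:1-mat", "1:1-pat"):
            present = [v for v in (c["A"], c["H"], c["B"])]
            two = sorted(range(3), key=lambda i: -present[i])[:2]
            out[m] = chi2_ratio_test([present[i] for i in sorted(two)], "1:1", alpha, m)
    return out


def detect_sdr(map_df: pd.DataFrame, seg: dict[str, SegTestResult],
               min_cluster: int = 3, max_gap_cM: float = 10.0):
    """Cluster distorted markers along each linkage group.

    ``map_df`` needs columns marker/lg/position.  A run extends across
    untested markers but is broken by a tested, non-distorted marker and by
    cM gaps > ``max_gap_cM`` between consecutive distorted members.  Runs
    with >= ``min_cluster`` members become :class:`SDRegion`; shorter runs
    are returned separately as singleton marker ids.
    """
    unknown = [m for m in seg if m not in set(map_df["marker"])]
    if unknown:
        raise ValueError(f"markers not on the map: {unknown[:5]}")
    regions: list[SDRegion] = []
    singletons: list[str] = []

    def flush(run):
        if not run:
            return
        if len(run) >= min_cluster:
            regions.append(SDRegion(
                lg=lg, start=run[0][1], end=run[-1][1],
                members=[m for m, _p in run], n_distorted=len(run)))
        else:
            singletons.extend(m for m, _p in run)

    for lg, sub in map_df.groupby("lg", sort=True):
        sub = sub.sort_values("position")
        run: list[tuple[str, float]] = []
        for m, pos in zip(sub["marker"], sub["position"]):
            res = seg.get(m)
            if res is None:
                continue  # untested markers neither extend nor break a run
            if res.distorted:
                if run and pos - run[-1][1] > max_gap_cM:
                    flush(run)
                    run = []
                run.append((m, float(pos)))
            else:
                flush(run)
                run = []
        flush(run)
    return regions, singletons


def _project(position: float, anchors_a: np.ndarray, anchors_b: np.ndarray) -> float:
    """Piecewise-linear map-to-map projection through shared anchor markers,
    constant extrapolation beyond the terminal anchors."""
    order = np.argsort(anchors_a)
    return float(np.interp(position, anchors_a[order], anchors_b[order]))


def contrast_pedigrees(sdr_f2: list[SDRegion],
                       distorted_g2f: pd.DataFrame,
                       distorted_g2m: pd.DataFrame,
                       anchors: pd.DataFrame,
                       slack_cM: float = 5.0) -> list[SDRegion]:
    """Inbreeding-revealed deleterious-locus candidates.

    Keeps the F2 SDRs whose interval, projected onto each outbred parental
    map through the anchor markers, contains no distorted marker there.
    ``distorted_g2f``/``distorted_g2m``: DataFrames (lg, position) of
    distorted markers on the two parental maps.  ``anchors``: columns lg,
    pos_f2, pos_g2f, pos_g2m.
    """
    out = []
    for region in sdr_f2:
        anc = anchors[anchors["lg"] == region.lg]
        if len(anc) < 2:
            raise ValueError(f"no usable anchors on {region.lg}: cannot project")
        clean = True
        for col, dist in (("pos_g2f", distorted_g2f), ("pos_g2m", distorted_g2m)):
            a = _project(region.start, anc["pos_f2"].to_numpy(), anc[col].to_numpy())
            b = _project(region.end, anc["pos_f2"].to_numpy(), anc[col].to_numpy())
            lo, hi = min(a, b) - slack_cM, max(a, b) + slack_cM
            hits = dist[(dist["lg"] == region.lg)
                        & (dist["position"] >= lo) & (dist["position"] <= hi)]
            if len(hits):
                clean = False
                break
        if clean:
            out.append(replace(region, origin_map="F2"))
    return out


def validate_sdr(candidate: SDRegion, second_cohort, alpha: float = 0.01,
                 min_cluster: int = 3) -> SDRegion:
    """Re-test a candidate SDR's member markers in an independent, larger
    cohort; validated iff >= ``min_cluster`` members remain distorted."""
    present = [m for m in candidate.members if m in second_cohort.calls.index]
    if not present:
        raise ValueError("no member marker genotyped in the validation cohort")
    seg = test_matrix(second_cohort, alpha)
    still = [m for m in present if m in seg and seg[m].distorted]
    status = "validated" if len(still) >= min_cluster else "rejected"
    return replace(candidate, status=status, n_distorted=len(still))


def classify_stage(distorted_female_map: bool, distorted_male_map: bool,
                   distorted_zygotic: bool) -> str:
    """Selection-stage call from where distortion shows up.

    Distortion on exactly one parental (gametic) map → prezygotic selection;
    distortion in zygotic ratios (e.g. a selfed F2, or both parental maps)
    → postzygotic; no evidence → undetermined.
    """
    parental = int(distorted_female_map) + int(distorted_male_map)
    if parental == 1 and not distorted_zygotic:
        return "prezygotic"
    if distorted_zygotic or parental == 2:
        return "postzygotic"
    return "undetermined"


def transmission_origin(gm, marker_ids: list[str], parent_haplotypes: np.ndarray,
                        origin_labels: tuple[str, str] = ("hap0", "hap1"),
                        alpha: float = 0.01):
    """Which grandparental allele is in deficit at an SDR.

    For a selfed F1 whose phased haplotypes descend from two known
    grandparents, F2 genotype class "A" is homozygous for the haplotype-0
    (first grandparent) allele and "B" for haplotype-1.  Tabulates class
    counts over the SDR markers and reports the homozygote class
    significantly below its 1:2:1 expectation, labelled with its
    grandparental origin.  Returns ``(label_or_None, per-marker table)``.
    """
    marker_index = {m: i for i, m in enumerate(gm.markers.index)}
    rows = []
    votes: list[str] = []
    for m in marker_ids:
        j = marker_index[m]
        if parent_haplotypes[0, j] == parent_haplotypes[1, j]:
            raise ValueError(f"parent not heterozygous (unphased?) at {m}")
        c = gm.counts(m)
        res = chi2_ratio_test((c["A"], c["H"], c["B"]), "1:2:1", alpha, m)
        total = sum(res.counts)
        exp_hom = total / 4.0
        deficit = None
        if res.distorted:
            if c["A"] < exp_hom and c["A"] <= c["B"]:
                deficit = origin_labels[0]
            elif c["B"] < exp_hom:
                deficit = origin_labels[1]
        rows.append((m, c["A"], c["H"], c["B"], res.p_value, deficit))
        if deficit:
            votes.append(deficit)
    table = pd.DataFrame(rows, columns=["marker", "n_AA", "n_AB", "n_BB",
                                        "p_value", "deficient_origin"])
    label = max(set(votes), key=votes.count) if votes else None
    return label, table
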