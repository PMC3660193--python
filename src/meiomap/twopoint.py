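"""Two-point linkage estimation, Kosambi distances and lightweight mapping.

Recombination fractions are estimated from pairwise-complete genotype calls:
directly (recombinants / informative meioses) for testcross (1:1) marker
pairs, and by EM over the 3x3 genotype table for codominant F2 (1:2:1)
pairs, trying both linkage phases and keeping the maximum-likelihood one.
The LOD score is the base-10 likelihood ratio of linkage at the estimated
fraction against independence (theta = 0.5).

Map construction is deliberately transparent rather than a re-implementation
of a multipoint package: groups are the transitive closure of pairs with
LOD >= threshold, ordering is greedy seriation (nearest-neighbour path)
refined by 2-opt on the summed adjacent recombination fractions, and
positions accumulate Kosambi distances between adjacent markers.  Less
informative markers can then be attached to their best-supported framework
position ("accessory" placement), as is conventional when merging 1:2:1
markers into a 1:1 pseudo-testcross framework map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseLinkage",
    "GeneticMap",
    "rf_testcross",
    "rf_f2",
    "kosambi_cm",
    "kosambi_rf",
    "haldane_rf",
    "group_markers",
    "order_markers",
    "place_accessory",
    "contig_consistency",
    "build_map",
]

_CODE_NUM = {"A": 0, "H": 1, "B": 2, "U": -1}


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_a: str
    marker_b: str
    rf: float
    lod: float
    n_informative: int
    phase: str  # "coupling" | "repulsion" | "n/a"


@dataclass
class GeneticMap:
    """Ordered markers with cM positions per linkage group.

    ``table`` columns: marker, lg, position, role ("framework"/"accessory"),
    nearest_framework, attach_dist_cM, attach_lod (the last three NaN/"" for
    framework markers).
    """

    table: pd.DataFrame

    def lgs(self) -> list[str]:
        return list(dict.fromkeys(self.table["lg"]))

    def lg_length(self, lg: str) -> float:
        sub = self.table[(self.table["lg"] == lg) & (self.table["role"] == "framework")]
        return float(sub["position"].max() - sub["position"].min())

    def lg_lengths(self) -> dict[str, float]:
        return {lg: self.lg_length(lg) for lg in self.lgs()}

    def framework_counts(self) -> dict[str, int]:
        fw = self.table[self.table["role"] == "framework"]
        return fw.groupby("lg").size().to_dict()

    def positions(self, lg: str) -> np.ndarray:
        sub = self.table[self.table["lg"] == lg]
        return np.sort(sub["position"].to_numpy(dtype=float))


def _encode(calls) -> np.ndarray:
    return np.array([_CODE_NUM.get(str(c), -1) for c in calls], dtype=np.int8)


# ---------------------------------------------------------------------------
# map functions

def kosambi_cm(theta: float) -> float:
    """Kosambi map distance in cM; defined for theta in [0, 0.5)."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must be in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


def kosambi_rf(cm: float) -> float:
    """Inverse Kosambi: recombination fraction for a distance in cM."""
    return 0.5 * math.tanh(2.0 * cm / 100.0)


def haldane_rf(cm: float) -> float:
    """Haldane map function (no interference); the simulator's truth scale."""
    return 0.5 * (1.0 - math.exp(-2.0 * cm / 100.0))


# ---------------------------------------------------------------------------
# recombination-fraction estimators

def _lod_testcross(n: int, r: int, theta: float) -> float:
    """log10 L(theta)/L(0.5) for a testcross with r recombinants of n."""
    lod = n * math.log10(2.0)
    if r > 0:
        lod += r * math.log10(theta) if theta > 0 else -math.inf
    if n - r > 0:
        lod += (n - r) * math.log10(1.0 - theta)
    return lod


def rf_testcross(calls_a, calls_b, marker_a: str = "a", marker_b: str = "b") -> PairwiseLinkage:
    """Two-point rf/LOD for two 1:1 markers informative for the same parent.

    Phase is unknown, so the recombinant class is whichever of
    (same-call, different-call) is the minority; theta-hat = R/n capped at
    0.5.  Boundary LODs use the 0*log 0 = 0 convention.
    """
    a, b = _encode(calls_a), _encode(calls_b)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no informative individuals for this pair")

    def _binarize(v):
        # each marker's two observed codes -> 0/1, so testcross markers with
        # different alphabets (e.g. {A,H} vs {A,B}) compare correctly
        codes = np.unique(v[v >= 0])
        return (v == codes.max()).astype(np.int8)

    mism = int((_binarize(a)[ok] != _binarize(b)[ok]).sum())
    r = min(mism, n - mism)
    phase = "coupling" if mism <= n - mism else "repulsion"
    theta = r / n
    lod = _lod_testcross(n, r, theta)
    return PairwiseLinkage(marker_a, marker_b, theta, max(lod, 0.0), n, phase)


def _f2_cell_model(theta: float):
    """Cell probabilities and recombinant-count decomposition for an F2 pair
    in coupling.  Returns a dict (ga, gb) -> list of (prob, n_recomb_gametes)
    contributions, where ga/gb are 0/1/2 genotype codes."""
    gam = {(0, 0): (1 - theta) / 2, (1, 1): (1 - theta) / 2,
           (0, 1): theta / 2, (1, 0): theta / 2}
    rec = {(0, 0): 0, (1, 1): 0, (0, 1): 1, (1, 0): 1}
    cells: dict[tuple[int, int], list[tuple[float, int]]] = {}
    for g1, p1 in gam.items():
        for g2, p2 in gam.items():
            key = (g1[0] + g2[0], g1[1] + g2[1])
            cells.setdefault(key, []).append((p1 * p2, rec[g1] + rec[g2]))
    return cells


def _f2_loglik(table: np.ndarray, theta: float) -> float:
    cells = _f2_cell_model(theta)
    ll = 0.0
    for (ga, gb), contribs in cells.items():
        n = table[ga, gb]
        if n:
            p = sum(p for p, _r in contribs)
            ll += n * math.log(max(p, 1e-300))
    return ll


def _f2_em(table: np.ndarray, theta0: float = 0.25, tol: float = 1e-10,
           max_iter: int = 500) -> float:
    n2 = 2.0 * table.sum()
    theta = theta0
    for _ in range(max_iter):
        cells = _f2_cell_model(theta)
        r_exp = 0.0
        for (ga, gb), contribs in cells.items():
            n = table[ga, gb]
            if n:
                tot = sum(p for p, _r in contribs)
                r_exp += n * sum(p * r for p, r in contribs) / max(tot, 1e-300)
        new = min(r_exp / n2, 0.5)
        if abs(new - theta) < tol:
            return new
        theta = new
    return theta


def rf_f2(calls_a, calls_b, marker_a: str = "a", marker_b: str = "b") -> PairwiseLinkage:
    """EM estimate of theta for two codominant 1:2:1 markers.

    Both phases are tried (the repulsion fit relabels one marker's alleles);
    the maximum-likelihood phase is kept.
    """
    a, b = _encode(calls_a), _encode(calls_b)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no informative individuals for this pair")
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (a[ok], b[ok]), 1.0)
    if (table.sum(axis=1) > 0).sum() == 1 or (table.sum(axis=0) > 0).sum() == 1:
        raise ValueError("degenerate table: one marker has a single genotype class")
    fits = []
    for phase, tab in (("coupling", table), ("repulsion", table[:, ::-1])):
        theta = _f2_em(tab)
        fits.append((_f2_loglik(tab, theta), theta, phase, tab))
    ll, theta, phase, tab = max(fits)
    lod = (ll - _f2_loglik(tab, 0.5)) / math.log(10.0)
    return PairwiseLinkage(marker_a, marker_b, theta, max(lod, 0.0), n, phase)


def pairwise_linkage(gm, markers: list[str] | None = None,
                     parent: str | None = None) -> list[PairwiseLinkage]:
    """All within-population two-point estimates.

    For a CP population pass ``parent`` = "mat"/"pat" to use that parent's
    1:1 testcross markers; F2 populations use all 1:2:1 markers.
    """
    if gm.population_type == "CP" and parent is not None:
        want = f"1:1-{parent}"
        ids = [m for m in gm.markers.index if gm.markers.loc[m, "seg_type"] == want]
        fn = rf_testcross
    else:
        ids = [m for m in gm.markers.index if gm.markers.loc[m, "seg_type"] == "1:2:1"]
        fn = rf_f2
    if markers is not None:
        keep = set(markers)
        ids = [m for m in ids if m in keep]
    out = []
    for ma, mb in combinations(ids, 2):
        try:
            out.append(fn(gm.calls.loc[ma], gm.calls.loc[mb], ma, mb))
        except ValueError:
            continue
    return out


def pairwise_rf_testcross(calls: pd.DataFrame):
    """Vectorised all-pairs testcross rf/LOD for 1:1 markers (rows).

    Returns (marker_ids, theta_matrix, lod_matrix, n_matrix).  Calls must use
    exactly two non-missing codes per marker.
    """
    ids = list(calls.index)
    enc = np.vstack([_encode(calls.loc[m]) for m in ids])
    valid = enc >= 0
    # map each row's two observed codes onto 0/1
    bin_ = np.zeros_like(enc, dtype=float)
    for i in range(enc.shape[0]):
        row = enc[i]
        codes = np.unique(row[row >= 0])
        hi = codes.max()
        bin_[i] = (row == hi).astype(float)
    V = valid.astype(float)
    B = bin_ * V
    n = V @ V.T
    mism = B @ (V - B).T + (V - B) @ B.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.minimum(mism, n - mism)
        theta = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        lod = (n * math.log10(2.0)
               + np.where(r > 0, r * np.log10(np.maximum(theta, 1e-300)), 0.0)
               + np.where(n - r > 0, (n - r) * np.log10(np.maximum(1.0 - theta, 1e-300)), 0.0))
    lod = np.where(n > 0, np.maximum(lod, 0.0), 0.0)
    return ids, theta, lod, n


# ---------------------------------------------------------------------------
# grouping / ordering

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def group_markers(linkages: list[PairwiseLinkage], lod_min: float = 3.0,
                  markers: list[str] | None = None) -> list[list[str]]:
    """Transitive closure of pairs with LOD >= lod_min -> linkage groups."""
    if markers is None:
        markers = sorted({m for lk in linkages for m in (lk.marker_a, lk.marker_b)})
    uf = _UnionFind(markers)
    for lk in linkages:
        if lk.lod >= lod_min:
            uf.union(lk.marker_a, lk.marker_b)
    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(uf.find(m), []).append(m)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def _rf_matrix(group: list[str], linkages: list[PairwiseLinkage]) -> np.ndarray:
    idx = {m: i for i, m in enumerate(group)}
    rf = np.full((len(group), len(group)), 0.5)
    np.fill_diagonal(rf, 0.0)
    for lk in linkages:
        if lk.marker_a in idx and lk.marker_b in idx:
            i, j = idx[lk.marker_a], idx[lk.marker_b]
            rf[i, j] = rf[j, i] = lk.rf
    return rf


def _path_cost(order: np.ndarray, rf: np.ndarray) -> float:
    return float(rf[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, rf: np.ndarray, max_pass: int = 40) -> np.ndarray:
    """2-opt on the open path; segment reversal i..j only changes the two
    boundary edges, so each candidate move is O(1)."""
    order = order.copy()
    n = len(order)
    improved = True
    passes = 0
    while improved and passes < max_pass:
        improved = False
        passes += 1
        for i in range(n - 1):
            a = order[i - 1] if i > 0 else -1
            for j in range(i + 1, n):
                b = order[j + 1] if j + 1 < n else -1
                delta = 0.0
                if a >= 0:
                    delta += rf[a, order[j]] - rf[a, order[i]]
                if b >= 0:
                    delta += rf[order[i], b] - rf[order[j], b]
                if delta < -1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
    return order


def order_markers(group: list[str], linkages: list[PairwiseLinkage],
                  lg_id: str = "LG1") -> GeneticMap:
    """Order one linkage group and assign cumulative Kosambi positions.

    Greedy nearest-neighbour seriation from each possible start, keeping the
    cheapest path, then 2-opt refinement.  Output orientation is canonical
    (first marker id < last marker id), so shuffled input yields the same map
    up to that fixed orientation.
    """
    group = sorted(group)
    rf = _rf_matrix(group, linkages)
    n = len(group)
    if n == 1:
        order = np.array([0])
    else:
        best = None
        for start in range(n):
            left = np.ones(n, dtype=bool)
            left[start] = False
            path = [start]
            work = rf.copy()
            for _ in range(n - 1):
                row = np.where(left, work[path[-1]], np.inf)
                nxt = int(row.argmin())
                path.append(nxt)
                left[nxt] = False
            path = np.array(path)
            cost = _path_cost(path, rf)
            if best is None or cost < best[0]:
                best = (cost, path)
        order = _two_opt(best[1], rf)
    if group[order[0]] > group[order[-1]]:
        order = order[::-1]
    pos = [0.0]
    for i, j in zip(order[:-1], order[1:]):
        step = kosambi_cm(min(rf[i, j], 0.499999))
        pos.append(pos[-1] + step)
    table = pd.DataFrame(
        {
            "marker": [group[i] for i in order],
            "lg": lg_id,
            "position": pos,
            "role": "framework",
            "nearest_framework": "",
            "attach_dist_cM": np.nan,
            "attach_lod": np.nan,
        }
    )
    return GeneticMap(table)


def place_accessory(framework: GeneticMap, marker: str,
                    linkages: list[PairwiseLinkage], lod_min: float = 3.0):
    """Attach a marker to its best-supported framework position.

    Chooses the framework marker with maximal two-point LOD (ties broken by
    smaller Kosambi distance); returns an updated map, or ``None`` (and the
    marker is reported unplaced) when nothing is linked at ``lod_min``.
    """
    fw = framework.table[framework.table["role"] == "framework"]
    cand = []
    for lk in linkages:
        pair = {lk.marker_a, lk.marker_b}
        if marker in pair:
            other = (pair - {marker}).pop()
            if other in set(fw["marker"]) and lk.lod >= lod_min:
                cand.append((lk.lod, -kosambi_cm(min(lk.rf, 0.499999)), other, lk))
    if not cand:
        return None
    _lod, _negd, anchor, lk = max(cand)
    row = fw[fw["marker"] == anchor].iloc[0]
    dist = kosambi_cm(min(lk.rf, 0.499999))
    new = pd.DataFrame(
        {
            "marker": [marker],
            "lg": [row["lg"]],
            "position": [row["position"]],
            "role": ["accessory"],
            "nearest_framework": [anchor],
            "attach_dist_cM": [dist],
            "attach_lod": [lk.lod],
        }
    )
    table = pd.concat([framework.table, new], ignore_index=True)
    table = table.sort_values(["lg", "position", "role"], kind="stable").reset_index(drop=True)
    return GeneticMap(table)


def build_map(gm, lod_min: float = 3.0, parent: str | None = None,
              with_accessory: bool = True) -> GeneticMap:
    """Group, order, and (optionally) attach accessory markers.

    For CP populations ``parent`` selects the 1:1 framework set ("mat" or
    "pat"); accessory markers are then the 1:2:1 intercross loci linked to
    the framework.  For F2 populations all 1:2:1 markers are framework.
    """
    if gm.population_type == "CP" and parent is not None:
        # vectorised all-pairs path for the 1:1 framework set
        want = f"1:1-{parent}"
        fw = [m for m in gm.markers.index if gm.markers.loc[m, "seg_type"] == want]
        ids, theta, lod, n = pairwise_rf_testcross(gm.calls.loc[fw])
        linkages = [
            PairwiseLinkage(ids[i], ids[j], float(theta[i, j]), float(lod[i, j]),
                            int(n[i, j]), "n/a")
            for i in range(len(ids)) for j in range(i + 1, len(ids))
            if n[i, j] > 0
        ]
    else:
        linkages = pairwise_linkage(gm, parent=parent)
    groups = group_markers(linkages, lod_min)
    tables = []
    for k, grp in enumerate(groups):
        sub = order_markers(grp, linkages, lg_id=f"LG{k + 1}")
        tables.append(sub.table)
    gmap = GeneticMap(pd.concat(tables, ignore_index=True))
    if with_accessory and gm.population_type == "CP" and parent is not None:
        inter = [m for m in gm.markers.index if gm.markers.loc[m, "seg_type"] == "1:2:1"]
        fw_ids = list(gmap.table["marker"])
        for m in inter:
            # against a 1:1 marker only the homozygous intercross calls are
            # informative; masking H reduces the pair to an exact testcross.
            acc_calls = gm.calls.loc[m].replace("H", "U")
            if (acc_calls != "U").sum() == 0:
                continue
            lks = []
            for f in fw_ids:
                try:
                    lks.append(rf_testcross(gm.calls.loc[f], acc_calls, f, m))
                except ValueError:
                    continue
            placed = place_accessory(gmap, m, lks, lod_min)
            if placed is not None:
                gmap = placed
    return gmap


# ---------------------------------------------------------------------------
# same-contig genotyping-error check

def genotyping_error_rate(n_events: int, n_comparisons: int) -> float:
    """Same-contig discordance rate as a percentage of comparisons."""
    if n_comparisons <= 0:
        raise ValueError("need at least one comparison")
    return 100.0 * n_events / n_comparisons


def contig_consistency(gm) -> tuple[int, int, float]:
    """Genotyping-error estimate from same-contig marker pairs.

    Markers from one contig are (virtually) zero recombination apart, so
    after re-orienting allele coding any call disagreement in an individual
    is a genotyping error.  Returns (n_comparisons, n_events, error % ).
    """
    swap = {"A": "B", "B": "A", "H": "H", "U": "U"}
    n_comp = 0
    n_evt = 0
    multi = [c for c, g in gm.markers.groupby("contig") if len(g) > 1]
    if not multi:
        raise ValueError("no contig has more than one marker")
    for contig in multi:
        ids = list(gm.markers.index[gm.markers["contig"] == contig])
        for ma, mb in combinations(ids, 2):
            a = gm.calls.loc[ma]
            b = gm.calls.loc[mb]
            ok = (a != "U") & (b != "U")
            direct = int((a[ok] != b[ok]).sum())
            flipped = int((a[ok] != b[ok].map(swap)).sum())
            n_comp += int(ok.sum())
            n_evt += min(direct, flipped)
    return n_comp, n_evt, genotyping_error_rate(n_evt, n_comp) if n_comp else 0.0
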