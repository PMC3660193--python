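"""Recombination hot/coldspot detection from marker density along a map.

On a saturated gene-based linkage map, local marker density is inversely
related to the local recombination rate: where recombination is suppressed,
markers pile up on the cM scale ("coldspots" of recombination, clusters of
markers); where it is elevated, markers spread out (recombination
"hotspots", gaps).  The detector:

1. picks a per-linkage-group Gaussian-kernel bandwidth h with a two-stage
   Sheather-Jones-type direct plug-in rule,
2. slides a window of width h in 1-cM steps and counts markers per window,
3. compares the genome-wide window-count distribution with Poisson(lambda),
   lambda = mean markers/window, and finds the count thresholds at which the
   pooled tail holds significantly more windows than expected (exact
   binomial tail test, Bonferroni-controlled over the scanned counts), and
4. merges threshold-crossing windows into hot/coldspot intervals, which can
   then be projected between maps through anchor markers and summarised as
   shared/specific sets with Jaccard indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LandscapeProfile",
    "select_bandwidth",
    "window_counts",
    "poisson_thresholds",
    "call_intervals",
    "build_profiles",
    "match_intervals",
    "jaccard",
    "summarize_features",
]

MIN_BANDWIDTH = 1.0  # cM floor for degenerate inputs


@dataclass
class Interval:
    kind: str  # "hotspot" | "coldspot"
    lg: str
    start: float
    end: float
    peak_count: int


@dataclass
class LandscapeProfile:
    lg: str
    bandwidth: float
    step: float
    windows: pd.DataFrame  # columns start, count
    lam: float | None = None
    k_cold: int | None = None
    k_hot: int | None = None
    intervals: list[Interval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# bandwidth

def _phi_deriv_sum(x: np.ndarray, g: float, order: int) -> float:
    """(1/n^2) * sum_ij phi^(order)_g(x_i - x_j) for a Gaussian kernel."""
    n = len(x)
    u = (x[:, None] - x[None, :]) / g
    if order == 4:
        h = u ** 4 - 6 * u ** 2 + 3  # He4
    elif order == 6:
        h = u ** 6 - 15 * u ** 4 + 45 * u ** 2 - 15  # He6
    else:
        raise ValueError(order)
    phi = np.exp(-0.5 * u ** 2) / math.sqrt(2 * math.pi)
    return float((h * phi).sum()) / (n ** 2 * g ** (order + 1))


def select_bandwidth(positions) -> float:
    """Two-stage direct-plug-in (Sheather-Jones-type) Gaussian bandwidth.

    Computed per linkage group.  With fewer than 5 markers, or a degenerate
    (zero-spread) sample, falls back to the Silverman rule-of-thumb with a
    1 cM floor and warns.
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25]))) if n > 1 else 0.0
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if n < 5 or sigma <= 0:
        warnings.warn("too few or degenerate positions: Silverman fallback")
        h = 0.9 * sigma * n ** (-0.2) if sigma > 0 else 0.0
        return max(h, MIN_BANDWIDTH)
    # stage 0: normal-scale estimate of psi8
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sigma ** 9)
    # stage 1: psi6 with pilot g6 = (-2*K6(0) / (psi8 * n))^(1/9), K6(0) = -15/sqrt(2pi)
    g6 = ((2.0 * 15.0 / math.sqrt(2 * math.pi)) / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _phi_deriv_sum(x, g6, 6)
    if psi6 >= 0:  # numerically degenerate sample; fall back
        warnings.warn("plug-in stage failed: Silverman fallback")
        return max(0.9 * sigma * n ** (-0.2), MIN_BANDWIDTH)
    # stage 2: psi4 with g4 = (-2*K4(0)/(psi6 * n))^(1/7), K4(0) = 3/sqrt(2pi)
    g4 = ((-2.0 * 3.0 / math.sqrt(2 * math.pi)) / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _phi_deriv_sum(x, g4, 4)
    if psi4 <= 0:
        warnings.warn("plug-in stage failed: Silverman fallback")
        return max(0.9 * sigma * n ** (-0.2), MIN_BANDWIDTH)
    h = (1.0 / (2.0 * math.sqrt(math.pi) * psi4 * n)) ** 0.2
    return max(h, MIN_BANDWIDTH)


# ---------------------------------------------------------------------------
# windows and thresholds

def window_counts(positions, lg_length: float, h: float, step: float = 1.0) -> pd.DataFrame:
    """Marker counts in windows [x, x+h), x = 0, step, 2*step, ...

    The final partial window is dropped so every window has equal width and
    the Poisson rate is comparable across windows; if h exceeds the linkage
    group length a single full-group window is returned with a warning.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pos = np.sort(np.asarray(positions, dtype=float))
    if h > lg_length:
        warnings.warn("bandwidth exceeds linkage-group length: single window")
        return pd.DataFrame({"start": [0.0], "count": [len(pos)]})
    starts = np.arange(0.0, lg_length - h + 1e-9, step)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + h, side="left")
    return pd.DataFrame({"start": starts, "count": hi - lo})


def poisson_thresholds(counts, alpha: float = 0.01, k_max: int | None = None):
    """Hot/coldspot count thresholds from the genome-wide window counts.

    Fits lambda = mean count; a *coldspot* threshold k_cold is the smallest
    k above lambda at which the observed number of windows with count >= k
    exceeds the Poisson expectation and that pooled tail is significant at
    ``alpha`` (exact binomial tail probability, Bonferroni-divided by the
    number of scanned k so a homogeneous map fires at most at rate alpha);
    symmetrically k_hot is the largest k below lambda for the lower tail
    (counts <= k).  Either is ``None`` when no count qualifies.  Returns
    ``(k_cold, k_hot, lambda, table)`` with the per-k tail table (the
    anti-conservative one-cell chi-square is reported there for
    reference).
    """
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    if n < 50:
        raise ValueError("need at least 50 windows for a stable Poisson fit")
    lam = float(counts.mean())
    if k_max is None:
        k_max = int(counts.max())
    rows = []
    k_cold = None
    # significance of the pooled tail uses the exact binomial tail
    # probability (tail windows ~ Binomial(n, Poisson tail prob)); the
    # one-cell chi-square is also reported but is anti-conservative when
    # the expected tail count is far below 1.  The threshold scan is
    # Bonferroni-controlled within each tail so that a homogeneous map
    # fires at most at rate alpha regardless of how many k are scanned.
    n_upper = max(1, k_max - int(math.floor(lam)))
    n_lower = max(1, int(math.ceil(lam)))
    for k in range(int(math.floor(lam)) + 1, k_max + 1):
        p_tail = stats.poisson.sf(k - 1, lam)
        obs = int((counts >= k).sum())
        exp = n * p_tail
        chi2 = (obs - exp) ** 2 / exp if exp > 0 else math.inf
        p = float(stats.binom.sf(obs - 1, n, p_tail)) if obs else 1.0
        rows.append(("upper", k, obs, exp, chi2, p))
        if obs > exp and p <= alpha / n_upper and k_cold is None:
            k_cold = k
    k_hot = None
    for k in range(int(math.ceil(lam)) - 1, -1, -1):
        p_tail = stats.poisson.cdf(k, lam)
        obs = int((counts <= k).sum())
        exp = n * p_tail
        chi2 = (obs - exp) ** 2 / exp if exp > 0 else math.inf
        p = float(stats.binom.sf(obs - 1, n, p_tail)) if obs else 1.0
        rows.append(("lower", k, obs, exp, chi2, p))
        if obs > exp and p <= alpha / n_lower and k_hot is None:
            k_hot = k
    table = pd.DataFrame(rows, columns=["tail", "k", "observed", "expected",
                                        "chi2", "p_value"])
    return k_cold, k_hot, lam, table


def call_intervals(profile: LandscapeProfile, k_cold: int | None,
                   k_hot: int | None) -> list[Interval]:
    """Merge threshold-crossing windows into maximal hot/coldspot intervals.

    Consecutive qualifying windows (one step apart) merge; the interval
    spans [first window start, last window start + h).
    """
    out: list[Interval] = []
    win = profile.windows
    for kind, cond in (("coldspot", (lambda c: k_cold is not None and c >= k_cold)),
                       ("hotspot", (lambda c: k_hot is not None and c <= k_hot))):
        run: list[tuple[float, int]] = []
        for start, count in zip(win["start"], win["count"]):
            if cond(count):
                if run and start - run[-1][0] > profile.step + 1e-9:
                    out.append(_mk_interval(kind, profile, run))
                    run = []
                run.append((float(start), int(count)))
            else:
                if run:
                    out.append(_mk_interval(kind, profile, run))
                    run = []
        if run:
            out.append(_mk_interval(kind, profile, run))
    return out


def _mk_interval(kind: str, profile: LandscapeProfile, run) -> Interval:
    counts = [c for _s, c in run]
    peak = max(counts) if kind == "coldspot" else min(counts)
    return Interval(kind, profile.lg, run[0][0], run[-1][0] + profile.bandwidth, peak)


def build_profiles(genetic_map, step: float = 1.0, alpha: float = 0.01,
                   framework_only: bool = True) -> dict[str, LandscapeProfile]:
    """Full landscape for one map: per-LG bandwidth and windows, genome-wide
    Poisson thresholds, per-LG called intervals."""
    profiles: dict[str, LandscapeProfile] = {}
    table = genetic_map.table
    if framework_only:
        table = table[table["role"] == "framework"]
    for lg in genetic_map.lgs():
        sub = table[table["lg"] == lg]
        pos = sub["position"].to_numpy(dtype=float)
        pos = pos - pos.min() if len(pos) else pos
        length = float(pos.max()) if len(pos) else 0.0
        h = select_bandwidth(pos)
        win = window_counts(pos, length, h, step)
        profiles[lg] = LandscapeProfile(lg, h, step, win)
    all_counts = np.concatenate([p.windows["count"].to_numpy() for p in profiles.values()])
    k_cold, k_hot, lam, _table = poisson_thresholds(all_counts, alpha)
    for p in profiles.values():
        p.lam, p.k_cold, p.k_hot = lam, k_cold, k_hot
        p.intervals = call_intervals(p, k_cold, k_hot)
    return profiles


# ---------------------------------------------------------------------------
# cross-map comparison

def _project(x: float, src: np.ndarray, dst: np.ndarray) -> float:
    order = np.argsort(src)
    return float(np.interp(x, src[order], dst[order]))


def match_intervals(feature_sets: dict[str, list[Interval]],
                    anchors: pd.DataFrame, kind: str):
    """Match features of one kind across maps through anchor projections.

    ``anchors`` columns: lg, pos_<map> for every map name in
    ``feature_sets``.  Two intervals on homologous linkage groups match when
    one's span, projected into the other map, overlaps.  Returns
    ``(pairs, venn)`` where pairs maps (mapA, mapB) to the matched index
    pairs and venn counts features private to one map, shared by exactly
    two, and shared by all (connected components over the match graph).
    """
    maps = list(feature_sets)
    feats = {m: [f for f in feature_sets[m] if f.kind == kind] for m in maps}
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, ma in enumerate(maps):
        for mb in maps[i + 1:]:
            matched = []
            for ia, fa in enumerate(feats[ma]):
                anc = anchors[anchors["lg"] == fa.lg]
                if len(anc) < 2:
                    warnings.warn(f"{fa.lg}: <2 anchors, excluded from matching")
                    continue
                src = anc[f"pos_{ma}"].to_numpy(dtype=float)
                dst = anc[f"pos_{mb}"].to_numpy(dtype=float)
                a, b = _project(fa.start, src, dst), _project(fa.end, src, dst)
                lo, hi = min(a, b), max(a, b)
                for ib, fb in enumerate(feats[mb]):
                    if fb.lg == fa.lg and fb.start <= hi and fb.end >= lo:
                        matched.append((ia, ib))
            pairs[(ma, mb)] = matched
    # connected components over (map, index) nodes
    nodes = [(m, i) for m in maps for i in range(len(feats[m]))]
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for (ma, mb), matched in pairs.items():
        for ia, ib in matched:
            ra, rb = find((ma, ia)), find((mb, ib))
            if ra != rb:
                parent[ra] = rb
    comps: dict[tuple, set[str]] = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v[0])
    venn = {"specific": 0, "shared_two": 0, "shared_all": 0}
    for members in comps.values():
        if len(members) == 1:
            venn["specific"] += 1
        elif len(members) == len(maps):
            venn["shared_all"] += 1
        else:
            venn["shared_two"] += 1
    return pairs, venn


def jaccard(features_a: list, features_b: list, matching: list[tuple[int, int]]):
    """|matched| / |union| for two feature sets under a computed matching.

    Matched features sharing an index on either side collapse to one
    correspondence.  Undefined (None) when both sets are empty.
    """
    if not features_a and not features_b:
        return None
    n_match = min(len({a for a, _b in matching}), len({b for _a, b in matching}))
    union = len(features_a) + len(features_b) - n_match
    return n_match / union


def summarize_features(per_map_counts, n_chromosomes: int) -> float:
    """Mean features per chromosome across maps, one decimal."""
    if n_chromosomes == 0:
        raise ValueError("n_chromosomes must be positive")
    counts = list(per_map_counts)
    return round(sum(counts) / (len(counts) * n_chromosomes), 1)
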