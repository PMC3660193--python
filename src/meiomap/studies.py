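"""Replicated simulation studies of the toolkit's operating characteristics.

These functions estimate, by Monte-Carlo over seeded replicates, the power
and calibration figures that characterise the analysis chain: recovery of a
planted viability locus through the full segregation-distortion pipeline
(discovery cohort -> inbred/outbred contrast -> larger validation cohort ->
stage and grandparental-origin call), the type-I rate of the per-marker
chi-square, two-point estimator bias, marker-order recovery, detection of
planted recombination hot/coldspots through estimated maps, and detection
of a genome-wide recombination-rate difference between genotypes.

Every study takes a single integer seed; replicate streams are derived from
it, so results are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import segregation as seg
from .compare import build_paired_rf, wilcoxon_paired, ztest_rf
from .landscape import build_profiles
from .simulate import CrossDesign, TrueMap, ViabilityLocus, simulate_cross, uniform_true_map
from .twopoint import build_map, rf_f2, rf_testcross

__all__ = [
    "sdr_recovery_study",
    "rf_bias_study",
    "order_recovery_study",
    "landscape_recovery_study",
    "null_feature_rate",
    "rate_difference_study",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _f1(n_markers: int) -> dict[str, np.ndarray]:
    return {"F1": np.vstack([np.zeros(n_markers, np.int8),
                             np.ones(n_markers, np.int8)])}


def _testcross_parents(n_markers: int) -> dict[str, np.ndarray]:
    """Mother heterozygous everywhere, father homozygous: every marker is a
    maternal 1:1 testcross locus."""
    return {"mother": np.vstack([np.zeros(n_markers, np.int8),
                                 np.ones(n_markers, np.int8)]),
            "father": np.zeros((2, n_markers), dtype=np.int8)}


# ---------------------------------------------------------------------------
# segregation-distortion pipeline

def sdr_recovery_study(seed: int = 1, n_seeds: int = 100, s: float = 1.0,
                       n_discovery: int = 69, n_validation: int = 380,
                       n_outbred: int = 83, alpha: float = 0.01,
                       min_cluster: int = 3, max_gap_cM: float = 15.0) -> dict:
    """Power of the full SDR pipeline against a planted viability locus.

    Per replicate: a selfed-F2 discovery cohort segregates a viability locus
    with fitness 1-s for one grandparental homozygote (LG1, 50 cM); a null
    outbred CP family provides the contrast; a larger selfed cohort
    validates.  A replicate succeeds when a validated SDR covering the
    locus is found, classified postzygotic, with the deficient allele
    traced to the correct grandparent.  Marker coordinates use the known
    simulated map so that the study isolates the distortion statistics.

    Also simulates a matching *null* selfed cohort per replicate to measure
    the per-marker false-flag rate at ``alpha``.

    Returns success_rate, per-step rates, and null_flag_rate.
    """
    tmap = uniform_true_map(2, 100.0, 5.0,
                            viability_locus=ViabilityLocus("LG1", 50.0, {"BB": 1.0 - s}))
    tmap_null = TrueMap(tmap.linkage_groups, tmap.markers)
    n_mk = len(tmap.markers)
    f1 = _f1(n_mk)
    cp_parents = {  # both parents heterozygous everywhere, phases random-free
        "mother": np.vstack([np.zeros(n_mk, np.int8), np.ones(n_mk, np.int8)]),
        "father": np.zeros((2, n_mk), dtype=np.int8),
    }
    map_df = tmap.markers.rename(columns={})[["marker", "lg", "position"]]
    anchors = pd.DataFrame({
        "lg": tmap.markers["lg"], "pos_f2": tmap.markers["position"],
        "pos_g2f": tmap.markers["position"], "pos_g2m": tmap.markers["position"],
    })
    counts = {"detected": 0, "contrasted": 0, "validated": 0,
              "postzygotic": 0, "origin_correct": 0, "success": 0}
    null_flags = 0
    null_tests = 0
    for sd in _seeds(seed, n_seeds):
        gm_f2 = simulate_cross(CrossDesign("F2_SELF", f1, n_discovery, sd), tmap)
        gm_cp = simulate_cross(CrossDesign("CP", cp_parents, n_outbred, sd + 1),
                               tmap_null)
        gm_val = simulate_cross(CrossDesign("F2_SELF", f1, n_validation, sd + 2), tmap)
        gm_null = simulate_cross(CrossDesign("F2_SELF", f1, n_validation, sd + 3),
                                 tmap_null)

        res_null = seg.test_matrix(gm_null, alpha)
        null_flags += sum(r.distorted for r in res_null.values())
        null_tests += len(res_null)

        res_f2 = seg.test_matrix(gm_f2, alpha)
        regions, _singles = seg.detect_sdr(map_df, res_f2, min_cluster, max_gap_cM)
        hit = [r for r in regions if r.lg == "LG1" and r.contains(50.0, slack=10.0)]
        if not hit:
            continue
        counts["detected"] += 1

        res_cp = seg.test_matrix(gm_cp, alpha)
        t = tmap.markers.set_index("marker")
        dist_cp = pd.DataFrame(
            [(t.loc[m, "lg"], float(t.loc[m, "position"]))
             for m, r in res_cp.items() if r.distorted],
            columns=["lg", "position"])
        cands = seg.contrast_pedigrees(hit, dist_cp, dist_cp, anchors)
        if not cands:
            continue
        counts["contrasted"] += 1

        val = seg.validate_sdr(cands[0], gm_val, alpha, min_cluster)
        if val.status != "validated":
            continue
        counts["validated"] += 1

        near = dist_cp[(dist_cp["lg"] == "LG1")
                       & (dist_cp["position"] - 50.0).abs().le(10.0)]
        stage = seg.classify_stage(len(near) > 0, len(near) > 0, True)
        if stage != "postzygotic":
            continue
        counts["postzygotic"] += 1

        label, _tbl = seg.transmission_origin(gm_val, val.members, f1["F1"],
                                              origin_labels=("hap0", "hap1"),
                                              alpha=alpha)
        if label != "hap1":
            continue
        counts["origin_correct"] += 1
        counts["success"] += 1
    return {
        "n_seeds": n_seeds,
        "success_rate": counts["success"] / n_seeds,
        "steps": {k: v / n_seeds for k, v in counts.items()},
        "null_flag_rate": null_flags / null_tests,
        "null_tests": null_tests,
    }


# ---------------------------------------------------------------------------
# estimator bias and ordering

def _haldane_cm(theta: float) -> float:
    return -50.0 * math.log(1.0 - 2.0 * theta)


def rf_bias_study(seed: int = 1, thetas=(0.05, 0.1, 0.2, 0.3), n: int = 10_000,
                  reps_testcross: int = 20, reps_f2: int = 12) -> dict:
    """Mean bias of the two-point estimators at known true theta.

    Marker distances are set so the Haldane (no-interference) recombination
    fraction equals each target theta; bias is averaged over enough
    replicates that the Monte-Carlo error (~0.001) is well below the 0.005
    scale on which estimator bias matters.
    """
    out_tc, out_f2 = {}, {}
    seeds = iter(_seeds(seed, len(thetas) * (reps_testcross + reps_f2)))
    for theta in thetas:
        d = _haldane_cm(theta)
        tmap = TrueMap([("LG1", d)], pd.DataFrame(
            {"marker": ["a", "b"], "lg": "LG1", "position": [0.0, d],
             "contig": ["c1", "c2"]}))
        est = []
        for _ in range(reps_testcross):
            gm = simulate_cross(
                CrossDesign("CP", _testcross_parents(2), n, next(seeds)), tmap)
            est.append(rf_testcross(gm.calls.loc["a"], gm.calls.loc["b"]).rf)
        out_tc[theta] = float(np.mean(est) - theta)
        est = []
        for _ in range(reps_f2):
            gm = simulate_cross(CrossDesign("F2_SELF", _f1(2), n, next(seeds)), tmap)
            est.append(rf_f2(gm.calls.loc["a"], gm.calls.loc["b"]).rf)
        out_f2[theta] = float(np.mean(est) - theta)
    return {
        "testcross_bias": out_tc,
        "f2_bias": out_f2,
        "max_abs_bias": max(abs(v) for d in (out_tc, out_f2) for v in d.values()),
    }


def order_recovery_study(seed: int = 1, n_markers: int = 10, spacing_cM: float = 2.0,
                         n_offspring: int = 500, reps: int = 5,
                         lod_min: float = 3.0) -> dict:
    """Fraction of replicates in which seriation recovers the simulated
    marker order (up to whole-group reversal)."""
    L = spacing_cM * (n_markers - 1)
    tmap = uniform_true_map(1, L, spacing_cM)
    truth = list(tmap.markers["marker"])
    ok = 0
    for sd in _seeds(seed, reps):
        gm = simulate_cross(
            CrossDesign("CP", _testcross_parents(len(truth)), n_offspring, sd), tmap)
        gmap = build_map(gm, lod_min, parent="mat", with_accessory=False)
        got = list(gmap.table["marker"])
        if len(gmap.lgs()) == 1 and (got == truth or got == truth[::-1]):
            ok += 1
    return {"recovery_rate": ok / reps, "reps": reps}


# ---------------------------------------------------------------------------
# recombination landscape

def landscape_recovery_study(seed: int = 1, reps: int = 5, effect: float = 3.0,
                             n_offspring: int = 500, alpha: float = 0.01) -> dict:
    """Recovery of planted recombination hot/coldspots through estimated maps.

    Genome: three 120-cM groups with testcross markers every 1 cM.  A
    recombination *hotspot* (rate x ``effect`` over [50, 70] cM of LG1 —
    markers spread out on the map, a marker-density gap) and a *coldspot*
    (rate / ``effect`` over [30, 90] of LG2 — markers pile up) are planted
    in the transmitting parent; region widths are chosen so that each
    feature's span on the *map* scale exceeds twice the kernel bandwidth
    (compression shrinks a coldspot's map footprint by ``effect``, so it
    needs a proportionally wider true region to stay resolvable).  Maps are
    re-estimated from two-point data and the landscape caller runs on the
    estimated maps; a planted feature counts as recovered when a called
    interval of the right kind overlaps markers truly inside the modified
    region.
    """
    n_lg, L, spacing = 3, 120.0, 1.0
    modifiers = {"mother": {"LG1": [(0.0, 50.0, 1.0), (50.0, 70.0, effect),
                                    (70.0, L, 1.0)],
                            "LG2": [(0.0, 30.0, 1.0), (30.0, 90.0, 1.0 / effect),
                                    (90.0, L, 1.0)]}}
    tmap = uniform_true_map(n_lg, L, spacing, rate_modifiers=modifiers)
    truth_mk = tmap.markers.set_index("marker")
    planted = {("hotspot", "LG1"), ("coldspot", "LG2")}
    recovered = 0
    total = 0
    for sd in _seeds(seed, reps):
        gm = simulate_cross(
            CrossDesign("CP", _testcross_parents(len(truth_mk)), n_offspring, sd),
            tmap)
        gmap = build_map(gm, lod_min=3.0, parent="mat", with_accessory=False)
        profiles = build_profiles(gmap, alpha=alpha)
        est = gmap.table.set_index("marker")
        # markers truly inside each planted region, with their estimated position
        regions = {"LG1": (50.0, 70.0), "LG2": (30.0, 90.0)}
        for kind, true_lg in planted:
            total += 1
            lo_t, hi_t = regions[true_lg]
            inside = [m for m in truth_mk.index
                      if truth_mk.loc[m, "lg"] == true_lg
                      and lo_t <= truth_mk.loc[m, "position"] <= hi_t
                      and m in est.index]
            found = False
            for p in profiles.values():
                base = est.loc[[m for m in est.index
                                if est.loc[m, "lg"] == p.lg], "position"].min()
                for iv in p.intervals:
                    if iv.kind != kind:
                        continue
                    lo, hi = iv.start + base, iv.end + base
                    n_in = sum(lo <= est.loc[m, "position"] <= hi for m in inside
                               if est.loc[m, "lg"] == p.lg)
                    if n_in >= 1:
                        found = True
            recovered += found
    return {"recovery_rate": recovered / total, "n_planted": total}


def null_feature_rate(seed: int = 1, n_seeds: int = 200, n_windows: int = 300,
                      lam: float = 4.0, alpha: float = 0.01) -> dict:
    """Fraction of homogeneous-Poisson replicates in which any hot/coldspot
    threshold fires at all (the caller's false-feature rate)."""
    from .landscape import poisson_thresholds

    rng = np.random.default_rng(seed)
    fired = 0
    for _ in range(n_seeds):
        counts = rng.poisson(lam, n_windows)
        k_cold, k_hot, _lam, _t = poisson_thresholds(counts, alpha)
        fired += (k_cold is not None) or (k_hot is not None)
    return {"false_feature_rate": fired / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# genome-wide rate difference

def rate_difference_study(seed: int = 1, factor: float = 1.2,
                          n_a: int = 69, n_b: int = 83,
                          n_lg: int = 12, spacing: float = 14.0,
                          length: float = 98.0) -> dict:
    """Detection of a genome-wide recombination-rate ratio between genotypes.

    Two testcross families share a marker panel; the transmitting parent of
    family A recombines ``factor`` times faster everywhere.  All within-LG
    pairwise recombination fractions are compared by paired Wilcoxon, and
    per-pair Z-tests are tallied by sign at P < 0.05.
    """
    tmap_b = uniform_true_map(n_lg, length, spacing)
    modifiers = {"mother": {lg: [(0.0, L, factor)] for lg, L in tmap_b.linkage_groups}}
    tmap_a = TrueMap(tmap_b.linkage_groups, tmap_b.markers, modifiers)
    n_mk = len(tmap_b.markers)
    sd = _seeds(seed, 2)
    gm_a = simulate_cross(CrossDesign("CP", _testcross_parents(n_mk), n_a, sd[0]),
                          tmap_a)
    gm_b = simulate_cross(CrossDesign("CP", _testcross_parents(n_mk), n_b, sd[1]),
                          tmap_b)
    common = pd.DataFrame({"marker": tmap_b.markers["marker"],
                           "lg": tmap_b.markers["lg"]})
    paired = build_paired_rf(gm_a, gm_b, common)
    v, p = wilcoxon_paired(paired["rf_a"], paired["rf_b"])
    n1 = float(paired["n_a"].mean())
    n2 = float(paired["n_b"].mean())
    sig_pos = sig_neg = 0
    for _i, row in paired.iterrows():
        try:
            zt = ztest_rf(min(row["rf_a"], 0.5), min(row["rf_b"], 0.5), n1, n2)
        except ValueError:
            continue
        if zt.p_value < 0.05:
            if zt.z > 0:
                sig_pos += 1
            else:
                sig_neg += 1
    return {
        "n_pairs": int(len(paired)),
        "wilcoxon_p": float(p),
        "median_diff": float(np.median(paired["rf_a"] - paired["rf_b"])),
        "z_sig_correct_sign": sig_pos,
        "z_sig_wrong_sign": sig_neg,
    }
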