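"""End-to-end analysis pipeline: simulate -> map -> distortion -> coverage ->
landscape -> comparison, driven by one declarative configuration.

The pipeline reproduces, on synthetic families, the complete analysis flow
used for SNP-array linkage maps in forest trees: an outbred full-sib family
(pseudo-testcross, one framework map per parent) and a selfed-F2 family are
simulated from the same ground-truth genome, maps are estimated from
two-point linkage, segregation distortion is tested and clustered, the
inbred/outbred contrast plus a larger validation cohort isolates
inbreeding-revealed viability loci, genome length/coverage statistics are
computed per map, the marker-density landscape is scanned for recombination
hot/coldspots, and recombination rates are compared between genotypes.

All randomness flows from the single ``seed`` key; two runs with the same
configuration are identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from . import coverage as cov
from . import landscape as lsc
from . import segregation as seg
from .io import write_genotypes, write_map
from .simulate import CrossDesign, TrueMap, ViabilityLocus, simulate_cross, uniform_true_map
from .twopoint import GeneticMap, build_map

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Demo configuration: a small three-chromosome genome, family sizes
    matching a typical SNP-array mapping study (83 outbred / 69 selfed
    offspring, 380-strong validation cohort), a recessive sublethal
    viability locus, and light genotyping noise."""
    return {
        "seed": 20130418,
        "map": {"n_lg": 3, "length_cM": 100.0, "spacing_cM": 5.0},
        "cp": {"n_offspring": 83, "frac_mat": 0.4, "frac_pat": 0.4},
        "f2": {"n_offspring": 69},
        "validation": {"n_offspring": 380},
        "viability": {"lg": "LG2", "position": 50.0, "fitness": {"BB": 0.2}},
        "noise": {"error_rate": 0.002, "missing_rate": 0.02},
        "analysis": {"alpha": 0.01, "lod_min": 3.0, "min_cluster": 3,
                     "max_gap_cM": 15.0, "coverage_X": 30.0},
    }


def _require(cfg: dict, key: str, section: str | None = None):
    src = cfg if section is None else cfg.get(section, {})
    if section is not None and section not in cfg:
        raise KeyError(f"missing configuration section {section!r}")
    if key not in src:
        where = f"{section}.{key}" if section else key
        raise KeyError(f"missing configuration key {where!r}")
    return src[key]


def _cp_parents(rng: np.random.Generator, n_markers: int, frac_mat: float,
                frac_pat: float) -> dict[str, np.ndarray]:
    """Phased CP parents: each marker is heterozygous in the mother only,
    the father only, or both (intercross)."""
    u = rng.random(n_markers)
    mom = np.zeros((2, n_markers), dtype=np.int8)
    dad = np.zeros((2, n_markers), dtype=np.int8)
    mom_het = u < frac_mat + (1 - frac_mat - frac_pat)
    dad_het = u >= frac_mat
    mom[1, mom_het] = 1
    dad[1, dad_het] = 1
    return {"mother": mom, "father": dad}


def _lg_homology(map_a: GeneticMap, map_b: GeneticMap) -> dict[str, str]:
    """Match linkage groups between two estimated maps by shared markers."""
    in_b = map_b.table.set_index("marker")["lg"]
    out = {}
    for lg in map_a.lgs():
        members = map_a.table.loc[map_a.table["lg"] == lg, "marker"]
        hits = [in_b[m] for m in members if m in in_b.index]
        if hits:
            out[lg] = pd.Series(hits).mode().iloc[0]
    return out


def _anchor_table(maps: dict[str, GeneticMap], ref: str) -> pd.DataFrame:
    """Shared-marker anchor positions, LG ids taken from the reference map."""
    tables = {name: m.table.set_index("marker") for name, m in maps.items()}
    ref_t = tables[ref]
    rows = []
    homology = {name: _lg_homology(maps[ref], maps[name]) for name in maps}
    for m in ref_t.index:
        lg = ref_t.loc[m, "lg"]
        row = {"marker": m, "lg": lg, f"pos_{ref}": float(ref_t.loc[m, "position"])}
        ok = True
        for name, t in tables.items():
            if name == ref:
                continue
            if m not in t.index or t.loc[m, "lg"] != homology[name].get(lg):
                ok = False
                break
            row[f"pos_{name}"] = float(t.loc[m, "position"])
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage and write the TSV/JSON report bundle to ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(_require(config, "seed"))
    rng = np.random.default_rng(seed)
    alpha = float(_require(config, "alpha", "analysis"))
    lod_min = float(_require(config, "lod_min", "analysis"))

    # ---- stage 1: ground truth + families -------------------------------
    mcfg = config["map"]
    vcfg = config.get("viability")
    vloc = ViabilityLocus(vcfg["lg"], float(vcfg["position"]),
                          dict(vcfg["fitness"])) if vcfg else None
    tmap = uniform_true_map(int(mcfg["n_lg"]), float(mcfg["length_cM"]),
                            float(mcfg["spacing_cM"]),
                            rate_modifiers=config.get("rate_modifiers", {}),
                            viability_locus=vloc)
    n_markers = len(tmap.markers)
    noise = config.get("noise", {})
    err, miss = float(noise.get("error_rate", 0)), float(noise.get("missing_rate", 0))

    cp_parents = _cp_parents(rng, n_markers, float(config["cp"]["frac_mat"]),
                             float(config["cp"]["frac_pat"]))
    f1 = {"H12": np.vstack([np.zeros(n_markers, np.int8), np.ones(n_markers, np.int8)])}
    sub = np.random.SeedSequence(seed).spawn(3)

    # the deleterious allele is carried by the selfed hybrid, not by the
    # unrelated outbred parents: no viability selection in the CP family
    tmap_cp = TrueMap(tmap.linkage_groups, tmap.markers,
                      tmap.rate_modifiers, None)
    gm_cp = simulate_cross(
        CrossDesign("CP", cp_parents, int(config["cp"]["n_offspring"]),
                    int(sub[0].generate_state(1)[0] % 2**31)), tmap_cp, err, miss)
    gm_f2 = simulate_cross(
        CrossDesign("F2_SELF", f1, int(config["f2"]["n_offspring"]),
                    int(sub[1].generate_state(1)[0] % 2**31)), tmap, err, miss)
    gm_val = simulate_cross(
        CrossDesign("F2_SELF", f1, int(config["validation"]["n_offspring"]),
                    int(sub[2].generate_state(1)[0] % 2**31)), tmap, err, miss)
    write_genotypes(gm_cp, out / "genotypes_cp.tsv")
    write_genotypes(gm_f2, out / "genotypes_f2.tsv")
    write_genotypes(gm_val, out / "genotypes_f2_validation.tsv")

    # ---- stage 2: maps ---------------------------------------------------
    maps = {
        "f2": build_map(gm_f2, lod_min),
        "g2f": build_map(gm_cp, lod_min, parent="mat"),
        "g2m": build_map(gm_cp, lod_min, parent="pat"),
    }
    for name, gmap in maps.items():
        write_map(gmap, out / f"map_{name}.tsv")
    anchors = _anchor_table(maps, "f2")
    anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)

    # ---- stage 3: segregation distortion ---------------------------------
    seg_res = {name: seg.test_matrix(g, alpha)
               for name, g in (("f2", gm_f2), ("cp", gm_cp))}
    seg_rows = [(name, r.marker, *r.counts, r.chi2, r.p_value, r.distorted)
                for name, d in seg_res.items() for r in d.values()]
    pd.DataFrame(seg_rows, columns=["population", "marker", "count_1", "count_2",
                                    "count_3", "chi2", "p_value", "distorted"]
                 ).fillna("").to_csv(out / "segregation_tests.tsv", sep="\t", index=False)

    min_cluster = int(config["analysis"]["min_cluster"])
    max_gap = float(config["analysis"]["max_gap_cM"])
    f2_map_df = maps["f2"].table[["marker", "lg", "position"]]
    f2_seg_on_map = {m: r for m, r in seg_res["f2"].items()
                     if m in set(f2_map_df["marker"])}
    sdrs, singles = seg.detect_sdr(f2_map_df, f2_seg_on_map, min_cluster, max_gap)

    def _distorted_positions(map_name: str, want_seg: str) -> pd.DataFrame:
        t = maps[map_name].table.set_index("marker")
        # report in the F2 map's LG labelling through homology
        hom = {v: k for k, v in _lg_homology(maps["f2"], maps[map_name]).items()}
        rows = []
        for m, r in seg_res["cp"].items():
            if r.distorted and m in t.index and str(
                    gm_cp.markers.loc[m, "seg_type"]) == want_seg:
                lg = hom.get(t.loc[m, "lg"], t.loc[m, "lg"])
                rows.append((lg, float(t.loc[m, "position"])))
        return pd.DataFrame(rows, columns=["lg", "position"])

    dist_g2f = _distorted_positions("g2f", "1:1-mat")
    dist_g2m = _distorted_positions("g2m", "1:1-pat")
    g2_anchors = anchors.rename(columns={"pos_g2f": "pos_g2f", "pos_g2m": "pos_g2m"})
    try:
        candidates = seg.contrast_pedigrees(sdrs, dist_g2f, dist_g2m, g2_anchors)
    except ValueError:
        candidates = []
    validated = []
    for cand in candidates:
        res = seg.validate_sdr(cand, gm_val, alpha, min_cluster)
        res.stage = seg.classify_stage(
            distorted_female_map=len(dist_g2f[dist_g2f["lg"] == cand.lg]) > 0,
            distorted_male_map=len(dist_g2m[dist_g2m["lg"] == cand.lg]) > 0,
            distorted_zygotic=res.status == "validated")
        if res.status == "validated":
            label, _tbl = seg.transmission_origin(
                gm_val, res.members, f1["H12"],
                origin_labels=("grandparent_hap0", "grandparent_hap1"), alpha=alpha)
            res.deficient_origin = label
        validated.append(res)
    pd.DataFrame(
        [(r.lg, r.start, r.end, ";".join(r.members), r.n_distorted, r.status,
          r.stage, r.deficient_origin or "") for r in validated],
        columns=["lg", "start_cM", "end_cM", "members", "n_distorted",
                 "status", "stage", "deficient_origin"],
    ).to_csv(out / "sdr_regions.tsv", sep="\t", index=False)

    # ---- stage 4: coverage -----------------------------------------------
    X = float(config["analysis"]["coverage_X"])
    cov_rows = []
    for name, gmap in maps.items():
        st = cov.coverage_stats(gmap, R=int(mcfg["n_lg"]), X=X)
        cov_rows.append((name, st.G0, st.Ge, st.Co, st.Ce, st.R, st.N, st.X,
                         st.density_cM_per_locus))
    cov_table = pd.DataFrame(cov_rows, columns=[
        "map", "G0_cM", "Ge_cM", "Co_percent", "Ce_fraction", "R", "N",
        "X_cM", "density_cM_per_locus"])
    cov_table.to_csv(out / "coverage.tsv", sep="\t", index=False)

    # ---- stage 5: recombination landscape --------------------------------
    profiles = {name: lsc.build_profiles(gmap, alpha=alpha)
                for name, gmap in maps.items()}
    track_rows, feat_rows = [], []
    for name, profs in profiles.items():
        for lg, p in profs.items():
            for s, c in zip(p.windows["start"], p.windows["count"]):
                track_rows.append((name, lg, p.bandwidth, float(s), int(c)))
            for iv in p.intervals:
                feat_rows.append((name, iv.kind, iv.lg, iv.start, iv.end,
                                  iv.peak_count))
    pd.DataFrame(track_rows, columns=["map", "lg", "bandwidth_cM",
                                      "window_start_cM", "marker_count"]
                 ).to_csv(out / "landscape_track.tsv", sep="\t", index=False)
    features = pd.DataFrame(feat_rows, columns=["map", "kind", "lg", "start_cM",
                                                "end_cM", "peak_count"])
    features.to_csv(out / "landscape_features.tsv", sep="\t", index=False)

    # ---- stage 6: recombination-rate comparison --------------------------
    distorted_ids = {m for d in seg_res.values() for m, r in d.items() if r.distorted}
    comp_rows = []
    z_rows = []
    for g2 in ("g2f", "g2m"):
        want = "1:1-mat" if g2 == "g2f" else "1:1-pat"
        common = gm_cp.markers.index[(gm_cp.markers["seg_type"] == want)]
        cm = pd.DataFrame({"marker": list(common),
                           "lg": [gm_f2.markers.loc[m, "lg"] for m in common]})
        try:
            paired = cmp.build_paired_rf(gm_f2, gm_cp, cm, exclude=distorted_ids)
        except ValueError:
            continue
        v, p = cmp.wilcoxon_paired(paired["rf_a"], paired["rf_b"])
        comp_rows.append((g2, len(paired), v, p,
                          float(np.median(paired["rf_a"] - paired["rf_b"]))))
        n1 = float(paired["n_a"].mean())
        n2 = float(paired["n_b"].mean())
        for _i, row in paired.iterrows():
            try:
                zt = cmp.ztest_rf(min(row["rf_a"], 0.5), min(row["rf_b"], 0.5), n1, n2)
            except ValueError:
                continue
            z_rows.append((g2, row["pair"], row["lg"], zt.theta1, zt.theta2,
                           zt.z, zt.p_value))
        paired.to_csv(out / f"paired_rf_f2_vs_{g2}.tsv", sep="\t", index=False)
    wilcoxon_table = pd.DataFrame(comp_rows, columns=[
        "comparison", "n_pairs", "wilcoxon_V", "p_value", "median_rf_diff"])
    wilcoxon_table.to_csv(out / "wilcoxon.tsv", sep="\t", index=False)
    pd.DataFrame(z_rows, columns=["comparison", "pair", "lg", "theta_f2",
                                  "theta_g2", "z", "p_value"]
                 ).to_csv(out / "ztests.tsv", sep="\t", index=False)

    # ---- summary ---------------------------------------------------------
    summary = {
        "seed": seed,
        "n_markers": int(n_markers),
        "n_lg_true": int(mcfg["n_lg"]),
        "maps": {name: {"n_lg": len(gmap.lgs()),
                        "n_markers": int(len(gmap.table)),
                        "length_cM": round(sum(gmap.lg_lengths().values()), 2)}
                 for name, gmap in maps.items()},
        "n_distorted_f2": int(sum(r.distorted for r in seg_res["f2"].values())),
        "n_sdr_candidates": len(candidates),
        "n_sdr_validated": sum(r.status == "validated" for r in validated),
        "sdr": [{"lg": r.lg, "status": r.status, "stage": r.stage,
                 "deficient_origin": r.deficient_origin} for r in validated],
        "coverage": cov_table.to_dict(orient="records"),
        "landscape_features": {name: int((features["map"] == name).sum())
                               for name in maps},
        "wilcoxon": wilcoxon_table.to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
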