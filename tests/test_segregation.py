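"""Segregation tests, SDR clustering, pedigree contrast, stage and origin."""

import math

import numpy as np
import pandas as pd
import pytest

from meiomap.segregation import test_matrix as seg_test_matrix
from meiomap.segregation import (
    SDRegion,
    chi2_ratio_test,
    classify_stage,
    contrast_pedigrees,
    detect_sdr,
    transmission_origin,
    validate_sdr,
)
from meiomap.simulate import CrossDesign, ViabilityLocus, simulate_cross, uniform_true_map

from conftest import f1_parent


class TestChiSquare:
    def test_exact_fit_121(self):
        res = chi2_ratio_test((25, 50, 25), "1:2:1")
        assert res.chi2 == 0.0 and res.p_value == 1.0 and not res.distorted

    def test_exact_fit_11(self):
        assert chi2_ratio_test((50, 50), "1:1").chi2 == 0.0

    def test_against_hand_computed_expectation(self):
        # n=69, expected (17.25, 34.5, 17.25); df=2 so p = exp(-chi2/2)
        res = chi2_ratio_test((23, 46, 0), "1:2:1")
        oracle = ((23 - 17.25) ** 2 / 17.25 + (46 - 34.5) ** 2 / 34.5
                  + (0 - 17.25) ** 2 / 17.25)
        assert res.chi2 == pytest.approx(oracle, abs=1e-12)
        assert res.p_value == pytest.approx(math.exp(-oracle / 2), rel=1e-9)
        assert res.distorted

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chi2_ratio_test((0, 0, 0), "1:2:1")
        with pytest.raises(ValueError):
            chi2_ratio_test((10, 10), "1:2:1")

    def test_low_expected_flagged(self):
        assert chi2_ratio_test((3, 4, 2), "1:2:1").low_expected


def _map_df(positions_by_lg):
    rows = []
    for lg, positions in positions_by_lg.items():
        for i, p in enumerate(positions):
            rows.append((f"{lg}_{i}", lg, p))
    return pd.DataFrame(rows, columns=["marker", "lg", "position"])


def _seg_flags(map_df, distorted_ids):
    out = {}
    for m in map_df["marker"]:
        dist = m in distorted_ids
        counts = (10, 50, 40) if dist else (25, 50, 25)
        out[m] = chi2_ratio_test(counts, "1:2:1", alpha=0.01, marker=m)
    return out


class TestDetectSDR:
    def test_adjacent_cluster_found(self):
        md = _map_df({"LG1": [0, 1, 3, 5, 40, 60]})
        seg = _seg_flags(md, {"LG1_0", "LG1_1", "LG1_2", "LG1_3"})
        regions, singles = detect_sdr(md, seg, min_cluster=3, max_gap_cM=10)
        assert len(regions) == 1
        assert regions[0].members == ["LG1_0", "LG1_1", "LG1_2", "LG1_3"]
        assert singles == []

    def test_three_neighborhoods_plus_singletons(self):
        # 27 distorted markers, 25 clustered at three places, 2 isolated
        lg1 = list(np.linspace(0, 100, 30))
        lg2 = list(np.linspace(0, 100, 30))
        md = _map_df({"LG1": lg1, "LG2": lg2})
        clusters = ([f"LG1_{i}" for i in range(0, 9)]        # 9 markers
                    + [f"LG1_{i}" for i in range(15, 23)]    # 8 markers
                    + [f"LG2_{i}" for i in range(10, 18)])   # 8 markers
        singles_true = ["LG1_28", "LG2_25"]
        seg = _seg_flags(md, set(clusters + singles_true))
        regions, singles = detect_sdr(md, seg, min_cluster=3, max_gap_cM=10)
        assert len(regions) == 3
        assert sum(r.n_distorted for r in regions) == 25
        assert sorted(singles) == sorted(singles_true)

    def test_no_distortion_empty(self):
        md = _map_df({"LG1": [0, 5, 10]})
        seg = _seg_flags(md, set())
        regions, singles = detect_sdr(md, seg)
        assert regions == [] and singles == []

    def test_non_distorted_marker_breaks_run(self):
        md = _map_df({"LG1": [0, 2, 4, 6, 8, 10]})
        seg = _seg_flags(md, {"LG1_0", "LG1_1", "LG1_2", "LG1_4", "LG1_5"})
        regions, singles = detect_sdr(md, seg, min_cluster=3, max_gap_cM=10)
        assert len(regions) == 1 and regions[0].n_distorted == 3
        assert sorted(singles) == ["LG1_4", "LG1_5"]

    def test_untested_markers_do_not_break_run(self):
        md = _map_df({"LG1": [0, 2, 4, 6]})
        seg = _seg_flags(md, {"LG1_0", "LG1_1", "LG1_3"})
        del seg["LG1_2"]  # untested, between distorted markers
        regions, _ = detect_sdr(md, seg, min_cluster=3, max_gap_cM=10)
        assert len(regions) == 1 and regions[0].n_distorted == 3

    def test_unmapped_marker_rejected(self):
        md = _map_df({"LG1": [0, 5]})
        seg = _seg_flags(md, set())
        seg["ghost"] = chi2_ratio_test((25, 50, 25), "1:2:1", marker="ghost")
        with pytest.raises(ValueError, match="not on the map"):
            detect_sdr(md, seg)


def _anchors():
    return pd.DataFrame({
        "marker": [f"a{i}" for i in range(6)],
        "lg": ["LG1"] * 3 + ["LG2"] * 3,
        "pos_f2": [0.0, 50.0, 100.0] * 2,
        "pos_g2f": [0.0, 50.0, 100.0] * 2,
        "pos_g2m": [0.0, 50.0, 100.0] * 2,
    })


class TestContrast:
    def _region(self, lg="LG2", start=40.0, end=60.0):
        return SDRegion(lg=lg, start=start, end=end,
                        members=["m1", "m2", "m3"], n_distorted=3)

    def test_clean_outbred_maps_keep_candidate(self):
        empty = pd.DataFrame(columns=["lg", "position"])
        out = contrast_pedigrees([self._region()], empty, empty, _anchors())
        assert len(out) == 1

    def test_same_position_distortion_excludes(self):
        hit = pd.DataFrame({"lg": ["LG2"], "position": [50.0]})
        empty = pd.DataFrame(columns=["lg", "position"])
        assert contrast_pedigrees([self._region()], hit, empty, _anchors()) == []
        assert contrast_pedigrees([self._region()], empty, hit, _anchors()) == []

    def test_distortion_elsewhere_keeps_candidate(self):
        far = pd.DataFrame({"lg": ["LG1"], "position": [50.0]})
        out = contrast_pedigrees([self._region()], far, far, _anchors())
        assert len(out) == 1

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["lg", "position"])
        assert contrast_pedigrees([], empty, empty, _anchors()) == []

    def test_missing_anchors_is_error(self):
        empty = pd.DataFrame(columns=["lg", "position"])
        with pytest.raises(ValueError, match="anchors"):
            contrast_pedigrees([self._region(lg="LG9")], empty, empty, _anchors())


class TestValidation:
    def test_identical_cohort_matches_discovery(self):
        vl = ViabilityLocus("LG1", 50.0, {"BB": 0.0})
        tmap = uniform_true_map(1, 100.0, 10.0, viability_locus=vl)
        gm = simulate_cross(CrossDesign("F2_SELF", f1_parent(len(tmap.markers)),
                                        380, 13), tmap)
        seg = seg_test_matrix(gm, 0.01)
        md = tmap.markers[["marker", "lg", "position"]]
        regions, _ = detect_sdr(md, seg, min_cluster=3, max_gap_cM=15)
        assert regions, "full lethality must produce an SDR at n=380"
        val = validate_sdr(regions[0], gm, 0.01, min_cluster=3)
        assert val.status == "validated"

    def test_no_members_in_cohort_is_error(self, small_f2):
        region = SDRegion("LG1", 0, 10, ["absent1", "absent2", "absent3"], 3)
        with pytest.raises(ValueError):
            validate_sdr(region, small_f2[1])

    def test_null_candidate_rejected(self, small_f2):
        # members not actually distorted in the cohort
        _tmap, gm = small_f2
        region = SDRegion("LG1", 0, 30, list(gm.calls.index[:3]), 3)
        assert validate_sdr(region, gm).status == "rejected"


class TestStageAndOrigin:
    @pytest.mark.parametrize(
        "female,male,zygotic,expected",
        [
            (True, False, False, "prezygotic"),
            (False, True, False, "prezygotic"),
            (False, False, True, "postzygotic"),
            (True, True, False, "postzygotic"),
            (False, False, False, "undetermined"),
        ],
    )
    def test_stage_rules(self, female, male, zygotic, expected):
        assert classify_stage(female, male, zygotic) == expected

    @pytest.mark.parametrize("lethal_class,expected_label",
                             [("BB", "corsica"), ("AA", "landes")])
    def test_origin_of_deficient_allele(self, lethal_class, expected_label):
        vl = ViabilityLocus("LG1", 50.0, {lethal_class: 0.0})
        tmap = uniform_true_map(1, 100.0, 25.0, viability_locus=vl)
        f1 = f1_parent(len(tmap.markers))
        gm = simulate_cross(CrossDesign("F2_SELF", f1, 380, 23), tmap)
        label, table = transmission_origin(
            gm, ["LG1_m002"], f1["F1"], origin_labels=("landes", "corsica"))
        assert label == expected_label
        assert len(table) == 1

    def test_neutral_gives_no_label(self, small_f2):
        _tmap, gm = small_f2
        label, _table = transmission_origin(
            gm, list(gm.calls.index[:3]), f1_parent(10)["F1"])
        assert label is None

    def test_unphased_parent_rejected(self, small_f2):
        _tmap, gm = small_f2
        hom = np.zeros((2, 10), dtype=np.int8)
        with pytest.raises(ValueError, match="heterozygous"):
            transmission_origin(gm, [gm.calls.index[0]], hom)
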