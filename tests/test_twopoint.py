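"""Two-point estimation, Kosambi conversions, grouping/ordering, contig QC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiomap.simulate import CrossDesign, TrueMap, simulate_cross, uniform_true_map
from meiomap.twopoint import (
    build_map,
    contig_consistency,
    group_markers,
    kosambi_cm,
    kosambi_rf,
    order_markers,
    pairwise_linkage,
    place_accessory,
    rf_f2,
    rf_testcross,
    PairwiseLinkage,
)

from conftest import f1_parent, tc_parents


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.25) == pytest.approx(25.0 * math.log(3.0), abs=1e-12)
        assert kosambi_rf(10.0) == pytest.approx(0.5 * math.tanh(0.2), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.49))
    def test_round_trip(self, theta):
        assert abs(kosambi_rf(kosambi_cm(theta)) - theta) < 1e-10

    def test_domain(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)


class TestTestcrossEstimator:
    def _calls(self, recomb_mask):
        # coupling: marker a all "A..H" pattern, marker b flips where recombinant
        a = np.where(np.arange(len(recomb_mask)) % 2 == 0, "A", "H")
        b = a.copy()
        b[recomb_mask] = np.where(b[recomb_mask] == "A", "H", "A")
        return a, b

    def test_perfect_linkage_boundary_lod(self):
        mask = np.zeros(100, dtype=bool)
        lk = rf_testcross(*self._calls(mask))
        assert lk.rf == 0.0
        assert lk.lod == pytest.approx(100 * math.log10(2.0), abs=1e-9)

    def test_lod_formula_at_r10_n100(self):
        mask = np.zeros(100, dtype=bool)
        mask[:10] = True
        lk = rf_testcross(*self._calls(mask))
        assert lk.rf == pytest.approx(0.10)
        expected = (100 * math.log10(2) + 10 * math.log10(0.1)
                    + 90 * math.log10(0.9))
        assert lk.lod == pytest.approx(expected, abs=1e-9)

    def test_independence_gives_zero_lod(self):
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        lk = rf_testcross(*self._calls(mask))
        assert lk.rf == 0.5
        assert lk.lod == 0.0

    def test_rf_capped_and_phase(self):
        mask = np.ones(100, dtype=bool)
        mask[:10] = False  # 90 "recombinant" => repulsion phase, rf 0.10
        lk = rf_testcross(*self._calls(mask))
        assert lk.rf == pytest.approx(0.10)
        assert lk.phase == "repulsion"

    def test_no_informative_individuals(self):
        with pytest.raises(ValueError):
            rf_testcross(["U", "U"], ["A", "H"])


def _f2_cell_probs_oracle(theta):
    """Independent enumeration of the coupling-phase F2 3x3 cell probs."""
    gam = {(0, 0): (1 - theta) / 2, (1, 1): (1 - theta) / 2,
           (0, 1): theta / 2, (1, 0): theta / 2}
    cells = np.zeros((3, 3))
    for (a1, b1), p1 in gam.items():
        for (a2, b2), p2 in gam.items():
            cells[a1 + a2, b1 + b2] += p1 * p2
    return cells


def _grid_search_oracle(table):
    best = (-np.inf, None)
    for phase in (False, True):
        tab = table[:, ::-1] if phase else table
        for theta in np.arange(1e-4, 0.5, 1e-4):
            ll = float((tab * np.log(_f2_cell_probs_oracle(theta))).sum())
            if ll > best[0]:
                best = (ll, theta)
    return best[1]


class TestF2Estimator:
    def test_identical_vectors_give_zero(self):
        calls = ["A", "H", "B", "H", "A", "B", "H", "H"] * 10
        lk = rf_f2(calls, calls)
        assert lk.rf < 1e-6

    def test_em_equals_grid_search_on_random_tables(self):
        rng = np.random.default_rng(0)
        code = np.array(["A", "H", "B"])
        for _ in range(20):
            theta = rng.uniform(0.02, 0.45)
            cells = _f2_cell_probs_oracle(theta)
            n = 400
            flat = rng.multinomial(n, cells.ravel())
            table = flat.reshape(3, 3)
            a = np.repeat(code, table.sum(axis=1))
            b = np.concatenate([np.repeat(code, row) for row in table])
            lk = rf_f2(a, b)
            assert abs(lk.rf - _grid_search_oracle(table.astype(float))) < 2e-4

    def test_parameter_recovery_at_n10000(self):
        # simulated pair at Haldane rf 0.10
        d = -50.0 * math.log(1 - 0.2)
        markers = pd.DataFrame({"marker": ["a", "b"], "lg": "LG1",
                                "position": [0.0, d], "contig": ["c1", "c2"]})
        tmap = TrueMap([("LG1", d)], markers)
        gm = simulate_cross(CrossDesign("F2_SELF", f1_parent(2), 10_000, 17), tmap)
        lk = rf_f2(gm.calls.loc["a"], gm.calls.loc["b"])
        assert abs(lk.rf - 0.10) < 0.01

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            rf_f2(["A"] * 20, list("AHB") * 6 + ["A", "A"])


@pytest.fixture(scope="module")
def two_lg_linkages():
    tmap = uniform_true_map(2, 40.0, 10.0)
    gm = simulate_cross(
        CrossDesign("CP", tc_parents(len(tmap.markers)), 300, 21), tmap)
    return gm, pairwise_linkage(gm, parent="mat")


class TestGroupingOrdering:

    def test_two_groups_recovered(self, two_lg_linkages):
        _gm, linkages = two_lg_linkages
        groups = group_markers(linkages, lod_min=3.0)
        assert len(groups) == 2
        assert all(len(g) == 5 for g in groups)
        # members share the simulated linkage group
        for g in groups:
            assert len({m.split("_")[0] for m in g}) == 1

    def test_twelve_group_genome_recovered(self):
        # chromosome-number recovery: 12 groups from a 12-LG genome at n=80.
        # LOD 5 controls the spurious-linkage tail over ~14k inter-group
        # phase-unknown pairs (LOD 3 would merge groups at this scale).
        tmap = uniform_true_map(12, 98.0, 7.0)
        gm = simulate_cross(
            CrossDesign("CP", tc_parents(len(tmap.markers)), 80, 77), tmap)
        gmap = build_map(gm, lod_min=5.0, parent="mat", with_accessory=False)
        assert len(gmap.lgs()) == 12

    def test_infinite_threshold_isolates_every_marker(self, two_lg_linkages):
        _gm, linkages = two_lg_linkages
        groups = group_markers(linkages, lod_min=math.inf)
        assert all(len(g) == 1 for g in groups)

    def test_true_order_recovered(self, small_cp):
        _tmap, gm = small_cp
        gmap = build_map(gm, parent="mat", with_accessory=False)
        got = list(gmap.table["marker"])
        truth = sorted(got)
        assert got == truth or got == truth[::-1]

    def test_two_marker_group(self):
        lk = [PairwiseLinkage("a", "b", 0.1, 10.0, 100, "coupling")]
        gmap = order_markers(["a", "b"], lk)
        pos = gmap.table.set_index("marker")["position"]
        assert pos["a"] == 0.0
        assert pos["b"] == pytest.approx(kosambi_cm(0.1))

    def test_permutation_invariance(self, small_cp):
        _tmap, gm = small_cp
        linkages = pairwise_linkage(gm, parent="mat")
        markers = [lk.marker_a for lk in linkages] + [lk.marker_b for lk in linkages]
        group = sorted(set(markers))
        rng = np.random.default_rng(5)
        orders = []
        for _ in range(3):
            shuffled = list(rng.permutation(group))
            orders.append(tuple(order_markers(shuffled, linkages).table["marker"]))
        assert len(set(orders)) == 1

    def test_map_length_close_to_kosambi_truth(self, small_cp):
        # 9 x 10 cM Haldane intervals; Kosambi-scale truth per interval
        _tmap, gm = small_cp
        gmap = build_map(gm, parent="mat", with_accessory=False)
        truth = 9 * kosambi_cm(0.5 * (1 - math.exp(-0.2)))
        assert gmap.lg_length("LG1") == pytest.approx(truth, rel=0.10)


class TestAccessoryPlacement:
    def test_attaches_to_nearest_framework(self):
        tmap = uniform_true_map(1, 40.0, 10.0)
        n = len(tmap.markers)
        # father also heterozygous at marker index 1 -> that one is 1:2:1
        parents = tc_parents(n)
        parents["father"][:, 1] = [0, 1]
        gm = simulate_cross(CrossDesign("CP", parents, 400, 31), tmap)
        gmap = build_map(gm, parent="mat", with_accessory=True)
        acc = gmap.table[gmap.table["role"] == "accessory"]
        assert list(acc["marker"]) == ["LG1_m001"]
        assert acc.iloc[0]["nearest_framework"] in ("LG1_m000", "LG1_m002")

    def test_unlinked_marker_unplaced(self, small_cp):
        _tmap, gm = small_cp
        gmap = build_map(gm, parent="mat", with_accessory=False)
        rng = np.random.default_rng(0)
        lks = [PairwiseLinkage("stray", m, 0.5, 0.0, 100, "n/a")
               for m in gmap.table["marker"]]
        assert place_accessory(gmap, "stray", lks, lod_min=3.0) is None

    def test_lod_tie_broken_by_distance(self, small_cp):
        _tmap, gm = small_cp
        gmap = build_map(gm, parent="mat", with_accessory=False)
        fw = list(gmap.table["marker"])[:2]
        lks = [PairwiseLinkage("acc", fw[0], 0.05, 8.0, 100, "n/a"),
               PairwiseLinkage("acc", fw[1], 0.20, 8.0, 100, "n/a")]
        placed = place_accessory(gmap, "acc", lks, lod_min=3.0)
        row = placed.table[placed.table["marker"] == "acc"].iloc[0]
        assert row["nearest_framework"] == fw[0]


class TestContigConsistency:
    def test_duplicated_markers_give_zero_rate(self):
        tmap = uniform_true_map(1, 20.0, 10.0, contig_copies=2)
        gm = simulate_cross(CrossDesign("F2_SELF", f1_parent(len(tmap.markers)),
                                        100, 3), tmap)
        n_comp, n_evt, rate = contig_consistency(gm)
        assert n_evt == 0 and rate == 0.0
        assert n_comp == 3 * 100  # 3 contigs x 1 pair x 100 individuals

    def test_injected_disagreements_counted(self):
        tmap = uniform_true_map(1, 20.0, 10.0, contig_copies=2)
        gm = simulate_cross(CrossDesign("F2_SELF", f1_parent(len(tmap.markers)),
                                        100, 3), tmap)
        # flip 5 calls of one duplicate
        m = gm.calls.index[0]
        col = gm.calls.columns[:5]
        gm.calls.loc[m, col] = gm.calls.loc[m, col].map(
            {"A": "H", "H": "A", "B": "H"})
        n_comp, n_evt, rate = contig_consistency(gm)
        assert n_evt == 5
        assert rate == pytest.approx(100.0 * 5 / n_comp)

    def test_allele_reorientation(self):
        # one duplicate recorded with swapped allele coding: still 0 errors
        tmap = uniform_true_map(1, 20.0, 10.0, contig_copies=2)
        gm = simulate_cross(CrossDesign("F2_SELF", f1_parent(len(tmap.markers)),
                                        100, 3), tmap)
        m = gm.calls.index[0]
        gm.calls.loc[m] = gm.calls.loc[m].map({"A": "B", "B": "A", "H": "H", "U": "U"})
        _c, n_evt, rate = contig_consistency(gm)
        assert n_evt == 0 and rate == 0.0

    def test_requires_multi_marker_contig(self, small_f2):
        with pytest.raises(ValueError):
            contig_consistency(small_f2[1])
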