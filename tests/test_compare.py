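"""Recombination-rate and marker-distribution comparisons between maps."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiomap.compare import (
    build_paired_rf,
    chi2_marker_distribution,
    collinearity_check,
    wilcoxon_paired,
    ztest_rf,
)
from meiomap.simulate import CrossDesign, TrueMap, simulate_cross, uniform_true_map
from meiomap.twopoint import GeneticMap

from conftest import tc_parents


class TestWilcoxon:
    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            v, p = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_p_matches_enumeration_at_n8(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.2, 0.05, 8)
        b = a - rng.normal(0.02, 0.05, 8)
        d = a - b
        _v, p = wilcoxon_paired(a, b)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                       for signs in product([0, 1], repeat=8)])
        p_oracle = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_systematic_shift_detected(self):
        rng = np.random.default_rng(4)
        b = rng.uniform(0.1, 0.4, 50)
        a = b + 0.05
        _v, p = wilcoxon_paired(a, b)
        assert p < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0], [1.0, 2.0])


class TestZTest:
    def test_equal_rates_give_zero(self):
        res = ztest_rf(0.2, 0.2, 69, 83)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_formula_oracle(self):
        res = ztest_rf(0.3, 0.1, 69, 83)
        var = 0.3 * 0.7 / 69 + 0.1 * 0.9 / 83
        assert res.z == pytest.approx(0.2 / math.sqrt(var), abs=1e-12)
        assert res.z == pytest.approx(3.11, abs=0.01)

    def test_antisymmetry(self):
        a = ztest_rf(0.3, 0.1, 69, 83)
        b = ztest_rf(0.1, 0.3, 83, 69)
        assert b.z == pytest.approx(-a.z, abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ztest_rf(0.0, 0.0, 69, 83)

    def test_domain(self):
        with pytest.raises(ValueError):
            ztest_rf(0.6, 0.1, 69, 83)


class TestPairedRf:
    def test_identical_populations_identical_lists(self, small_cp):
        _tmap, gm = small_cp
        common = pd.DataFrame({"marker": gm.calls.index,
                               "lg": gm.markers["lg"].to_numpy()})
        paired = build_paired_rf(gm, gm, common)
        assert len(paired) == 45  # C(10, 2)
        assert (paired["rf_a"] == paired["rf_b"]).all()

    def test_distorted_markers_excluded(self, small_cp):
        _tmap, gm = small_cp
        common = pd.DataFrame({"marker": gm.calls.index,
                               "lg": gm.markers["lg"].to_numpy()})
        drop = {gm.calls.index[0]}
        paired = build_paired_rf(gm, gm, common, exclude=drop)
        assert len(paired) == 36  # C(9, 2)
        assert not any(m in p for m in drop for p in paired["pair"])

    def test_no_common_markers_rejected(self, small_cp):
        _tmap, gm = small_cp
        common = pd.DataFrame({"marker": ["nope1", "nope2"], "lg": ["LG1", "LG1"]})
        with pytest.raises(ValueError):
            build_paired_rf(gm, gm, common)


class TestMarkerDistribution:
    def test_proportional_counts_fit(self):
        chi2, df, p = chi2_marker_distribution([100.0, 200.0], [10, 20])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_hand_computed_chi2(self):
        lengths = [100.0] * 12
        counts = [20] * 11 + [10]
        chi2, df, _p = chi2_marker_distribution(lengths, counts)
        e = sum(counts) / 12
        oracle = sum((o - e) ** 2 / e for o in counts)
        assert chi2 == pytest.approx(oracle, abs=1e-9)
        assert df == 11

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            chi2_marker_distribution([100.0], [10])


def _map_from(positions: dict) -> GeneticMap:
    rows = [(m, lg_pos[0], lg_pos[1], "framework", "", np.nan, np.nan)
            for m, lg_pos in positions.items()]
    return GeneticMap(pd.DataFrame(
        rows, columns=["marker", "lg", "position", "role",
                       "nearest_framework", "attach_dist_cM", "attach_lod"]))


class TestCollinearity:
    def test_identical_maps_clean_report(self):
        m = _map_from({"a": ("LG1", 0.0), "b": ("LG1", 10.0), "c": ("LG1", 20.0)})
        rep = collinearity_check(m, m)
        assert rep["n_discordances"] == 0
        assert rep["rank_correlation"]["LG1"] == pytest.approx(1.0)

    def test_lg_reassignment_detected(self):
        a = _map_from({"a": ("LG1", 0.0), "b": ("LG1", 10.0), "c": ("LG1", 20.0)})
        b = _map_from({"a": ("LG1", 0.0), "b": ("LG2", 10.0), "c": ("LG1", 20.0)})
        rep = collinearity_check(a, b)
        assert rep["lg_assignment_discordances"] == ["b"]

    def test_adjacent_swap_detected(self):
        a = _map_from({"a": ("LG1", 0.0), "b": ("LG1", 10.0), "c": ("LG1", 20.0)})
        b = _map_from({"a": ("LG1", 0.0), "b": ("LG1", 20.0), "c": ("LG1", 10.0)})
        rep = collinearity_check(a, b)
        assert len(rep["order_discordances"]) == 1

    def test_whole_group_reversal_is_not_discordance(self):
        a = _map_from({"a": ("LG1", 0.0), "b": ("LG1", 10.0), "c": ("LG1", 20.0)})
        b = _map_from({"a": ("LG1", 20.0), "b": ("LG1", 10.0), "c": ("LG1", 0.0)})
        rep = collinearity_check(a, b)
        assert rep["n_discordances"] == 0


class TestNullCalibration:
    def test_ztest_null_rejection_near_nominal(self):
        # same recombination landscape in both families: per-pair Z-tests
        # should reject at about the nominal rate.  (The genome-wide
        # Wilcoxon over the same pairs is NOT null-calibrated: all pairs of
        # one map share its meioses, so its p-value overstates evidence --
        # see docs/methods.md.)
        from meiomap.studies import rate_difference_study
        sig = tot = 0
        for s in range(10):
            r = rate_difference_study(seed=3000 + s, factor=1.0)
            sig += r["z_sig_correct_sign"] + r["z_sig_wrong_sign"]
            tot += r["n_pairs"]
        assert 0.02 <= sig / tot <= 0.09


class TestMapLengthComparison:
    def test_planted_inflation_detected_across_seeds(self):
        # 1.2x genome-wide inflation; Wilcoxon over 12 LG lengths should
        # reject at alpha=0.05 in >=80% of replicates at these family sizes.
        # Grouping uses LOD 5: with ~15k phase-unknown inter-group pairs the
        # spurious-linkage tail at LOD 3 would merge true groups.
        tmap_b = uniform_true_map(12, 98.0, 7.0)
        mod = {"mother": {lg: [(0.0, L, 1.2)] for lg, L in tmap_b.linkage_groups}}
        tmap_a = TrueMap(tmap_b.linkage_groups, tmap_b.markers, mod)
        n_mk = len(tmap_b.markers)
        rejections = 0
        n_seeds = 10
        for s in range(n_seeds):
            from meiomap.twopoint import build_map
            gm_a = simulate_cross(CrossDesign("CP", tc_parents(n_mk), 69, 100 + s),
                                  tmap_a)
            gm_b = simulate_cross(CrossDesign("CP", tc_parents(n_mk), 83, 200 + s),
                                  tmap_b)
            # pair homologous groups by length rank, keeping the 12 largest
            # in case an unlucky replicate splits a group
            len_a = sorted(build_map(gm_a, 5.0, parent="mat",
                                     with_accessory=False).lg_lengths().values(),
                           reverse=True)[:12]
            len_b = sorted(build_map(gm_b, 5.0, parent="mat",
                                     with_accessory=False).lg_lengths().values(),
                           reverse=True)[:12]
            _v, p = wilcoxon_paired(len_a, len_b)
            rejections += p < 0.05
        assert rejections >= 0.8 * n_seeds
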