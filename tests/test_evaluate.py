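"""Lesion decomposition, per-case metrics, cohort tables, calibration curves."""

import dataclasses

import numpy as np
import pytest

import oracles
import focalmargin as fm
from focalmargin import margins
from focalmargin.margins import MarginMask
from focalmargin.voxelgeom import Mask, VoxelGrid
from conftest import make_toy_case


def _mask(values, grid):
    return Mask(grid, values)


def _margin(values, grid, kind="test"):
    return MarginMask(Mask(grid, values), {"kind": kind})


class TestDecomposeLesions:
    def test_single_component_no_satellites(self):
        grid = VoxelGrid((12, 12, 12))
        truth = np.zeros(grid.shape, dtype=bool)
        truth[4:7, 4:7, 4:7] = True
        dec = fm.decompose_lesions(_mask(truth, grid))
        assert not dec.satellites
        np.testing.assert_array_equal(dec.index.values, truth)

    def test_one_mm_gap_merges(self):
        grid = VoxelGrid((12, 12, 12))
        truth = np.zeros(grid.shape, dtype=bool)
        truth[2:5, 2:5, 2:5] = True
        truth[2:5, 2:5, 6] = True  # 1 mm from z=4 face (gap voxel at z=5)
        dec = fm.decompose_lesions(_mask(truth, grid))
        assert not dec.satellites
        assert dec.merged_labels == [2]
        assert dec.index.count == truth.sum()

    def test_three_mm_gap_is_satellite(self):
        grid = VoxelGrid((14, 14, 14))
        truth = np.zeros(grid.shape, dtype=bool)
        truth[2:7, 2:7, 2:6] = True          # 100 voxels: index
        truth[3:5, 3:5, 9:12] = True         # 12 voxels, 3 mm away (z 6,7,8 empty)
        dec = fm.decompose_lesions(_mask(truth, grid))
        assert len(dec.satellites) == 1
        assert dec.index.count == 100
        gap = oracles.brute_surface_distance(dec.index.values,
                                             dec.satellites[0].values,
                                             grid.spacing_mm)
        assert gap >= 2.0

    def test_chained_merge_is_transitive(self):
        """A component pulled into the index can pull in a further one."""
        grid = VoxelGrid((16, 6, 6))
        truth = np.zeros(grid.shape, dtype=bool)
        truth[0:4, 0:3, 0:3] = True    # index (36 voxels)
        truth[5, 1, 1] = True          # 1 mm from index
        truth[7, 1, 1] = True          # 2 mm from previous, 3 mm from index
        dec = fm.decompose_lesions(_mask(truth, grid))
        assert sorted(dec.merged_labels) == [2, 3] or len(dec.satellites) == 1

    def test_empty_truth_rejected(self):
        grid = VoxelGrid((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            fm.decompose_lesions(_mask(np.zeros(grid.shape, dtype=bool), grid))


class TestCaseMetrics:
    def test_whole_gland_margin_is_perfect(self, toy_case):
        m = _margin(toy_case.gland.values.copy(), toy_case.grid)
        cm = fm.case_metrics(m, toy_case)
        assert cm.sensitivity == 1.0
        assert cm.extent_missed_mm == 0.0
        assert cm.negative_margin_all and cm.negative_margin_index
        assert cm.failure_attribution == "none"

    def test_empty_margin_convention(self, toy_case):
        m = _margin(np.zeros(toy_case.grid.shape, dtype=bool), toy_case.grid)
        cm = fm.case_metrics(m, toy_case)
        assert cm.sensitivity == 0.0
        assert cm.specificity == 1.0
        assert cm.empty_margin
        # penetration measured from the gland boundary (documented convention)
        assert cm.extent_missed_mm > 0

    def test_extent_missed_matches_brute_force(self):
        """Crafted case: margin covers the lesion except a 3-voxel tongue."""
        case = make_toy_case(shape=(12, 12, 12))
        truth = np.zeros(case.grid.shape, dtype=bool)
        truth[5:8, 5:8, 3:9] = True
        truth &= case.gland.values
        case = dataclasses.replace(case, truth_cs=Mask(case.grid, truth),
                                   lesion_labels=None, cem=None)
        marg = truth.copy()
        marg[5:8, 5:8, 3:6] = marg[5:8, 5:8, 3:6]  # keep
        marg[6, 6, 6:9] = False  # miss a 3-voxel tongue
        m = _margin(marg, case.grid)
        cm = fm.case_metrics(m, case)
        expected = oracles.brute_extent_missed(truth, marg,
                                               case.grid.spacing_mm)
        assert cm.extent_missed_mm == pytest.approx(expected)
        assert not cm.negative_margin_all

    def test_negative_margin_equivalences(self, small_cohort, small_lookup):
        """negative_margin_all <=> extent 0 <=> sensitivity 1 on real margins."""
        cases, _ = small_cohort
        for case in cases[:6]:
            for t in (0.1, 0.3, 0.5):
                cm = fm.case_metrics(fm.threshold_margin(case, t), case)
                assert cm.negative_margin_all == (cm.extent_missed_mm == 0.0)
                assert cm.negative_margin_all == (cm.sensitivity == 1.0)
                if cm.negative_margin_all:
                    assert cm.negative_margin_index

    def test_adding_voxels_never_hurts(self, small_cohort):
        cases, _ = small_cohort
        case = cases[0]
        rng = np.random.default_rng(0)
        base = fm.threshold_margin(case, 0.4).mask.values
        extra = base | (rng.random(case.grid.shape) < 0.05)
        cm_base = fm.case_metrics(_margin(base, case.grid), case)
        cm_big = fm.case_metrics(_margin(extra, case.grid), case)
        assert cm_big.sensitivity >= cm_base.sensitivity
        assert cm_big.extent_missed_mm <= cm_base.extent_missed_mm

    def test_satellite_attribution(self):
        case = make_toy_case(shape=(16, 16, 16))
        truth = np.zeros(case.grid.shape, dtype=bool)
        truth[3:8, 3:8, 3:8] = True     # index
        truth[11:13, 11:13, 11:13] = True  # satellite, far away
        truth &= case.gland.values
        case = dataclasses.replace(case, truth_cs=Mask(case.grid, truth))
        marg = np.zeros(case.grid.shape, dtype=bool)
        marg[2:9, 2:9, 2:9] = True  # covers index only
        cm = fm.case_metrics(_margin(marg, case.grid), case)
        assert cm.negative_margin_index and not cm.negative_margin_all
        assert cm.failure_attribution == "satellite"

    def test_truthless_slab_not_evaluable(self):
        case = make_toy_case()
        case = dataclasses.replace(case, slab=(14, 15))  # outside the lesion
        m = _margin(case.gland.values.copy(), case.grid)
        assert not fm.case_metrics(m, case).evaluable


@pytest.fixture(scope="module")
def table_setup(small_cohort, small_lookup):
    cases, _ = small_cohort
    cohort = cases[:8]
    defaults = {c.case_id: fm.default_margin(small_lookup, c)[0]
                for c in cohort}
    recipes = {
        "default_ai": lambda c: defaults[c.case_id],
        "roi": margins.roi_margin,
        "roi_expanded": margins.expanded_roi_margin,
        "hemigland": margins.hemigland_margin,
    }
    return cohort, recipes, fm.cohort_table(cohort, recipes)


class TestCohortTable:
    def test_rates_equal_hand_recount(self, table_setup):
        cohort, recipes, table = table_setup
        for name in table.index:
            flags = []
            for c in cohort:
                try:
                    m = recipes[name](c)
                except ValueError:
                    continue
                flags.append(fm.case_metrics(m, c).negative_margin_all)
            assert table.loc[name, "negative_margin_any_count"] == sum(flags)
            assert table.loc[name, "negative_margin_any_rate"] == \
                pytest.approx(np.mean(flags))
            assert table.loc[name, "n"] == len(flags)

    def test_ai_dominates_raw_roi_sensitivity(self, table_setup):
        cohort, recipes, table = table_setup
        for c in cohort:
            ai = fm.case_metrics(recipes["default_ai"](c), c).sensitivity
            roi = fm.case_metrics(recipes["roi"](c), c).sensitivity
            assert ai >= roi
        assert table.loc["default_ai", "sensitivity_mean"] >= \
            table.loc["roi", "sensitivity_mean"]

    def test_self_comparison_p_is_one(self, small_cohort, small_lookup):
        cases, _ = small_cohort
        cohort = cases[:5]
        defaults = {c.case_id: fm.default_margin(small_lookup, c)[0]
                    for c in cohort}
        recipes = {"default_ai": lambda c: defaults[c.case_id],
                   "clone": lambda c: defaults[c.case_id]}
        table = fm.cohort_table(cohort, recipes)
        assert table.loc["clone", "sensitivity_p_vs_ref"] == 1.0
        assert table.loc["clone", "negative_margin_any_p_vs_ref"] == 1.0

    def test_hemigland_row_uses_reduced_denominator(self, small_cohort,
                                                    small_lookup):
        cases, _ = small_cohort
        cohort = cases[:8]
        n_candidates = sum(1 for c in cohort if fm.candidate_hemispheres(c))
        defaults = {c.case_id: fm.default_margin(small_lookup, c)[0]
                    for c in cohort}
        table = fm.cohort_table(cohort, {
            "default_ai": lambda c: defaults[c.case_id],
            "hemigland": margins.hemigland_margin})
        assert table.loc["hemigland", "n"] == n_candidates


class TestCalibrationCurve:
    def test_self_calibration_identity(self, small_cohort, small_lookup):
        cases, _ = small_cohort
        rep = fm.calibration_curve(small_lookup, cases, allow_overlap=True)
        np.testing.assert_allclose(rep.observed, rep.predicted)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.median_abs_error == 0.0

    def test_overlap_rejected(self, small_cohort, small_lookup):
        cases, _ = small_cohort
        with pytest.raises(ValueError, match="both calibration and test"):
            fm.calibration_curve(small_lookup, cases,
                                 calibration_ids={c.case_id for c in cases})

    def test_degenerate_lookup_reports_nan(self, small_cohort):
        cases, _ = small_cohort
        flat = fm.ECSLookup(np.linspace(0, 1, 11), np.full(11, 0.5),
                            n_cases=5)
        with pytest.warns(UserWarning, match="degenerate"):
            rep = fm.calibration_curve(flat, cases[:3])
        assert np.isnan(rep.r_squared)
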