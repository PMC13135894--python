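"""Classification, extents, scenario deltas, expansion flag, priority."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermshift import (
    AlignmentError,
    GridDefinition,
    PriorityThresholds,
    THSGrid,
    class_extents,
    classify,
    delta_ths,
    priority_category,
    range_expansion_flag,
    summarize_change,
)
from thermshift.change import CLASS_LABELS


def ths_grid(values, lats=None):
    v = np.asarray(values, float)
    lats = np.linspace(60, -60, v.shape[0]) if lats is None else np.asarray(lats, float)
    g = GridDefinition(lats, np.linspace(-150, 150, v.shape[1]))
    return THSGrid(grid=g, values=v)


class TestClassify:
    @pytest.mark.parametrize("value, label", [
        (0.0, "Minimal"), (0.1, "Minimal"),
        (0.2, "Minor"), (0.39, "Minor"),
        (0.4, "Moderate"), (0.5, "Moderate"),
        (0.6, "Major"), (0.79, "Major"),
        (0.8, "Massive"), (1.0, "Massive"),
    ])
    def test_boundary_convention(self, value, label):
        out = classify(ths_grid([[value]]))
        assert out.label_at(int(out.codes[0, 0])) == label

    def test_nodata_propagates_as_zero_code(self):
        out = classify(ths_grid([[0.5, np.nan]]))
        assert out.codes[0, 1] == 0

    def test_dense_unit_grid_covers_all_five_classes(self):
        vals = np.linspace(0, 1, 1001).reshape(7, 143)
        codes = classify(ths_grid(vals)).codes
        assert set(np.unique(codes)) == {1, 2, 3, 4, 5}

    def test_out_of_range_values_rejected(self):
        g = GridDefinition(np.array([0.0]), np.array([0.0]))
        ths = THSGrid.__new__(THSGrid)  # bypass container validation deliberately
        object.__setattr__(ths, "grid", g)
        object.__setattr__(ths, "values", np.array([[1.2]]))
        with pytest.raises(ValueError, match="outside"):
            classify(ths)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_classification_idempotent_and_complete(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(5, 8))
        out1 = classify(ths_grid(vals))
        out2 = classify(ths_grid(vals))
        assert np.array_equal(out1.codes, out2.codes)
        assert np.all((out1.codes >= 1) & (out1.codes <= 5))


class TestClassExtents:
    def test_single_class_grid_gets_total_area(self):
        ext = class_extents(classify(ths_grid(np.full((3, 4), 0.5))))
        areas = ths_grid(np.full((3, 4), 0.5)).grid.cell_areas_km2()
        moderate = ext.loc[ext["class"] == "Moderate", "area_km2"].item()
        assert moderate == pytest.approx(areas.sum())
        assert ext.loc[ext["class"] != "Moderate", "area_km2"].sum() == 0.0

    def test_cosine_latitude_weighting(self):
        # same class at 0° and 60°: areas in ratio 1 : cos(60°) = 1 : 0.5
        grid = ths_grid([[0.9], [0.9]], lats=[0.0, 60.0])
        areas = grid.grid.cell_areas_km2()
        assert areas[1, 0] / areas[0, 0] == pytest.approx(0.5)

    def test_all_nodata_grid_zero_extents(self):
        ext = class_extents(classify(ths_grid(np.full((2, 2), np.nan))))
        assert (ext["area_km2"] == 0).all() and (ext["n_cells"] == 0).all()

    def test_partition_sums_to_total_unmasked_area(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=(12, 24))
        vals[0, :5] = np.nan
        grid = ths_grid(vals)
        ext = class_extents(classify(grid))
        total = grid.grid.cell_areas_km2()[np.isfinite(vals)].sum()
        assert ext["area_km2"].sum() == pytest.approx(total, rel=1e-6)


class TestDeltaTHS:
    def test_identical_scenarios_zero_everywhere(self):
        a = ths_grid(np.full((3, 3), 0.4))
        diff, stats = delta_ths(a, ths_grid(np.full((3, 3), 0.4)))
        assert np.all(diff == 0.0)
        assert stats == {"mean": 0.0, "min": 0.0, "max": 0.0}

    def test_uniform_shift_recovered(self):
        base = ths_grid(np.full((2, 2), 0.5))
        fut = ths_grid(np.full((2, 2), 0.6))
        _, stats = delta_ths(base, fut)
        assert stats["mean"] == pytest.approx(0.1)

    def test_disjoint_masks_are_alignment_error(self):
        base = ths_grid([[0.5, np.nan]])
        fut = ths_grid([[np.nan, 0.5]])
        with pytest.raises(AlignmentError):
            delta_ths(base, fut)


class TestRangeExpansion:
    def test_identical_scenarios_non_expanding(self):
        a = ths_grid(np.full((2, 2), 0.7))
        flag, b, f = range_expansion_flag(a, ths_grid(np.full((2, 2), 0.7)))
        assert not flag and b == f

    def test_added_qualifying_cell_expands(self):
        base = ths_grid([[0.7, 0.3]])
        fut = ths_grid([[0.7, 0.65]])
        flag, b, f = range_expansion_flag(base, fut)
        assert flag and f > b

    def test_lost_qualifying_area_non_expanding(self):
        base = ths_grid([[0.7, 0.65]])
        fut = ths_grid([[0.7, 0.3]])
        flag, *_ = range_expansion_flag(base, fut)
        assert not flag

    def test_extent_weakly_monotone_in_qualifying_cells(self):
        base = ths_grid([[0.7, 0.59, 0.2]])
        more = ths_grid([[0.7, 0.60, 0.2]])  # 0.6 itself qualifies
        _, b, f = range_expansion_flag(base, more)
        assert f >= b


class TestPriority:
    def test_strong_decline_is_priority(self):
        cat, r = priority_category(100.0, 70.0)
        assert cat == "Priority" and r == pytest.approx(-30.0)

    def test_moderate_increase_is_surveillance(self):
        cat, r = priority_category(100.0, 110.0)
        assert cat == "Surveillance" and r == pytest.approx(10.0)

    def test_stability_is_no_issue(self):
        assert priority_category(100.0, 100.0)[0] == "NoIssue"

    def test_new_habitat_from_zero_baseline_is_priority(self):
        cat, r = priority_category(0.0, 5.0)
        assert cat == "Priority" and np.isinf(r)

    def test_zero_both_is_no_issue(self):
        assert priority_category(0.0, 0.0)[0] == "NoIssue"

    def test_malformed_thresholds_rejected(self):
        with pytest.raises(ValueError):
            priority_category(1.0, 2.0, PriorityThresholds(low=20.0, high=5.0))
        with pytest.raises(ValueError):
            priority_category(1.0, 2.0, PriorityThresholds(low=-1.0, high=5.0))


class TestZeroChangeIdentity:
    def test_identical_scenarios_all_null_changes(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=(8, 10))
        vals[2, 3] = np.nan
        base = ths_grid(vals)
        fut = ths_grid(vals.copy())
        s = summarize_change("sp", base, fut)
        assert (s.class_table["absolute_change_km2"] == 0).all()
        filled = s.class_table["percent_change"].dropna()
        assert (filled == 0).all()
        assert s.delta_mean == 0.0 and s.delta_min == 0.0 and s.delta_max == 0.0
        assert not s.range_expanding
        assert s.priority == "NoIssue"
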