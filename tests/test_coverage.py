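"""Protected-area processing, occurrence-weighted coverage, targets, seasons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

from stemcover import (
    clean_protected_polygons,
    coverage_table,
    dissolve_by_priority,
    filter_layer,
    intersect_pa_grid,
    make_protected_layer,
    percent_protected,
    percent_protected_thresholded,
    range_adjusted_target,
    season_of_week,
    season_window,
    weekly_range_area,
)
from tests.conftest import make_uniform_world


def feature(geom, status="Designated", desig_type="National", designation="Park",
            iucn_cat="II", rep_area=None):
    return {
        "geometry": geom, "status": status, "desig_type": desig_type,
        "designation": designation, "iucn_cat": iucn_cat, "rep_area_km2": rep_area,
    }


class TestCleanPolygons:
    def test_unimplemented_status_removed(self):
        feats = pd.DataFrame([feature(box(0, 0, 10, 10), status="Proposed")])
        assert len(clean_protected_polygons(feats)) == 0

    def test_point_buffered_to_reported_area(self):
        feats = pd.DataFrame([feature(Point(50, 50), rep_area=314.159)])
        out = clean_protected_polygons(feats)
        assert len(out) == 1
        geom = out["geometry"].iloc[0]
        # circle of radius sqrt(A/pi) = 10 km
        assert geom.area == pytest.approx(314.159, rel=1e-3)
        assert geom.bounds == pytest.approx((40, 40, 60, 60), abs=0.1)

    def test_point_without_area_dropped(self):
        feats = pd.DataFrame([feature(Point(0, 0))])
        assert len(clean_protected_polygons(feats)) == 0

    def test_biosphere_and_unassigned_designation_removed(self):
        feats = pd.DataFrame(
            [
                feature(box(0, 0, 1, 1), designation="UNESCO-MAB Biosphere Reserve"),
                feature(box(0, 0, 1, 1), desig_type="Not Assigned"),
                feature(box(0, 0, 1, 1), desig_type="OECM"),
                feature(box(0, 0, 1, 1)),
            ]
        )
        assert len(clean_protected_polygons(feats)) == 1

    def test_empty_input_empty_output(self):
        assert len(clean_protected_polygons(pd.DataFrame(columns=["geometry", "status"]))) == 0

    def test_unknown_category_label_raises(self):
        feats = pd.DataFrame([feature(box(0, 0, 1, 1), iucn_cat="VII")])
        with pytest.raises(KeyError, match="VII"):
            clean_protected_polygons(feats)


class TestDissolve:
    def test_strict_category_wins_overlap(self):
        cleaned = pd.DataFrame(
            [
                {"geometry": box(0, 0, 10, 10), "iucn_cat": "Ia"},
                {"geometry": box(5, 0, 15, 10), "iucn_cat": "V"},
            ]
        )
        out = dissolve_by_priority(cleaned).set_index("group")
        assert out.loc["I-IV", "area_km2"] == pytest.approx(100.0)
        assert out.loc["V-VI", "area_km2"] == pytest.approx(50.0)  # overlap ceded

    def test_disjoint_same_group_areas_add(self):
        cleaned = pd.DataFrame(
            [
                {"geometry": box(0, 0, 2, 2), "iucn_cat": "V"},
                {"geometry": box(10, 10, 12, 12), "iucn_cat": "VI"},
            ]
        )
        out = dissolve_by_priority(cleaned).set_index("group")
        assert out.loc["V-VI", "area_km2"] == pytest.approx(8.0)

    def test_total_area_bounded_by_union(self):
        rects = [box(i, 0, i + 2, 2) for i in range(0, 10, 1)]  # heavy overlap
        cats = ["Ia", "II", "IV", "V", "VI", "unassigned", "III", "Ib", "V", "II"]
        cleaned = pd.DataFrame({"geometry": rects, "iucn_cat": cats})
        out = dissolve_by_priority(cleaned)
        from shapely.ops import unary_union

        union_area = unary_union(rects).area
        assert out["area_km2"].sum() == pytest.approx(union_area)


class TestIntersectGrid:
    def test_half_cell_fraction(self):
        world = make_uniform_world(2, 2)
        dissolved = dissolve_by_priority(
            pd.DataFrame([{"geometry": box(0, 0, 10, 5), "iucn_cat": "II"}])
        )
        layer = intersect_pa_grid(dissolved, world).set_index("cell_id")
        assert layer.loc[0, "fraction_I_IV"] == pytest.approx(0.5)
        assert layer.loc[1, "fraction_total"] == 0.0

    def test_three_and_a_half_cells(self):
        world = make_uniform_world(4, 1)
        dissolved = dissolve_by_priority(
            pd.DataFrame([{"geometry": box(0, 0, 35, 10), "iucn_cat": "IV"}])
        )
        layer = intersect_pa_grid(dissolved, world)
        assert layer["fraction_I_IV"].tolist() == pytest.approx([1, 1, 1, 0.5])

    def test_no_polygons_all_zero(self):
        world = make_uniform_world(2, 2)
        layer = intersect_pa_grid(dissolve_by_priority(pd.DataFrame(columns=["geometry", "iucn_cat"])), world)
        assert (layer["fraction_total"] == 0).all()


class TestFilterLayer:
    def _layer(self):
        return pd.DataFrame(
            {
                "cell_id": [0],
                "fraction_I_IV": [0.1],
                "fraction_V_VI": [0.2],
                "fraction_undesignated": [0.3],
                "fraction_total": [0.6],
            }
        )

    def test_all_groups_identity(self):
        layer = self._layer()
        out = filter_layer(layer, ("I-IV", "V-VI", "undesignated"))
        assert out["fraction_total"].iloc[0] == pytest.approx(0.6)

    def test_strict_plus_undesignated(self):
        out = filter_layer(self._layer(), ("I-IV", "undesignated"))
        assert out["fraction_total"].iloc[0] == pytest.approx(0.4)

    def test_filtered_never_exceeds_unfiltered(self, world40):
        layer = make_protected_layer(world40, 0.3, seed=5)
        out = filter_layer(layer, ("I-IV",))
        assert (out["fraction_total"] <= layer["fraction_total"] + 1e-12).all()

    def test_empty_include_rejected(self):
        with pytest.raises(ValueError):
            filter_layer(self._layer(), ())


def preds(p, cells=None, week=20, sp="SP1"):
    p = np.asarray(p, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": cells if cells is not None else np.arange(len(p)),
            "week": week,
            "species_id": sp,
            "p_occ": p,
        }
    )


def layer_of(fracs):
    fracs = np.asarray(fracs, dtype=float)
    return pd.DataFrame({"cell_id": np.arange(len(fracs)), "fraction_total": fracs})


class TestPercentProtected:
    def test_worked_example_cell_contribution(self):
        # One square with 10% of summed occurrence, half protected -> 5 points.
        p = np.array([0.1, 0.9])
        a = np.array([0.5, 0.0])
        assert percent_protected(preds(p), layer_of(a)) == pytest.approx(5.0)

    def test_fully_protected_world_gives_100(self):
        assert percent_protected(preds([0.3, 0.2]), layer_of([1, 1])) == pytest.approx(100.0)

    def test_weighted_sum_oracle(self):
        p = np.array([0.6, 0.3, 0.1])
        a = np.array([0.0, 0.5, 1.0])
        assert percent_protected(preds(p), layer_of(a)) == pytest.approx(25.0)

    def test_all_zero_occurrence_rejected(self):
        with pytest.raises(ValueError):
            percent_protected(preds([0.0, 0.0]), layer_of([0.5, 0.5]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10),
        scale=st.floats(min_value=1e-3, max_value=1e3),
        data=st.data(),
    )
    def test_scale_invariance_and_bounds(self, p, scale, data):
        if sum(p) == 0:
            p[0] = 0.5
        a = data.draw(
            st.lists(st.floats(min_value=0, max_value=1), min_size=len(p), max_size=len(p))
        )
        base = percent_protected(preds(p), layer_of(a))
        scaled = percent_protected(preds(np.array(p) * scale), layer_of(a))
        assert 0 <= base <= 100
        assert base == pytest.approx(scaled, rel=1e-9, abs=1e-9)


class TestThresholdedCoverage:
    def test_uniform_fraction_below_and_above_threshold(self):
        p = preds([0.4, 0.6])
        assert percent_protected_thresholded(p, layer_of([0.3, 0.3]), 0.5) == 0.0
        assert percent_protected_thresholded(p, layer_of([0.3, 0.3]), 0.1) == 100.0

    def test_indicator_weighting_oracle(self):
        p = preds([0.5, 0.5])
        out = percent_protected_thresholded(p, layer_of([0.6, 0.05]), 0.5)
        assert out == pytest.approx(50.0)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            percent_protected_thresholded(preds([0.5]), layer_of([0.5]), 0.0)


class TestRangeAndTargets:
    def test_range_area_counts_occupied_cells(self):
        p = preds(np.concatenate([np.full(2500, 0.5), np.zeros(10)]))
        assert weekly_range_area(p, 100.0) == pytest.approx(250_000.0)
        assert weekly_range_area(preds([0.0, 0.0]), 100.0) == 0.0

    def test_target_endpoints(self):
        assert range_adjusted_target(3_619_119, 17) == 17.0
        assert range_adjusted_target(1000, 17) == 100.0
        assert range_adjusted_target(500, 30) == 100.0
        assert range_adjusted_target(250_000, 30) == 30.0
        assert range_adjusted_target(500_000, 30) == 30.0

    def test_log_midpoint_matches_linear_in_log_oracle(self):
        mid = math.sqrt(1000 * 250_000)
        assert range_adjusted_target(mid, 17) == pytest.approx(58.5, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=0, max_value=1e7),
        b=st.floats(min_value=0, max_value=1e7),
        base=st.sampled_from([17.0, 30.0]),
    )
    def test_target_monotone_and_bounded(self, a, b, base):
        ta, tb = range_adjusted_target(a, base), range_adjusted_target(b, base)
        assert base <= ta <= 100
        if a <= b:
            assert ta >= tb

    def test_nonstandard_base_warns_but_computes(self):
        with pytest.warns(UserWarning):
            assert range_adjusted_target(1e6, 25.0) == 25.0


class TestSeasons:
    def test_window_spans_interior_dips(self):
        win = season_window(np.array([10, 30, 20, 100, 20]), cutoff=0.25)
        assert (win.first_week, win.last_week) == (2, 4)

    def test_constant_series_full_span(self):
        win = season_window(np.full(10, 3.0))
        assert (win.first_week, win.last_week) == (1, 10)

    def test_argmax_week_inside_window(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.random(30)
            win = season_window(s)
            assert win.contains(int(np.argmax(s)) + 1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            season_window(np.zeros(5))

    @pytest.mark.parametrize(
        "week,season",
        [(18, "spring"), (19, "breeding"), (31, "breeding"), (32, "autumn"),
         (2, "spring"), (50, "autumn")],
    )
    def test_season_bins(self, week, season):
        assert season_of_week(week) == season


class TestCoverageTable:
    def test_uniform_occurrence_equals_mean_protected_fraction(self, world40):
        layer = make_protected_layer(world40, 0.25, seed=9)
        rows = []
        for week in range(20, 24):
            rows.append(preds(np.full(world40.n_cells, 0.4), week=week))
        table = coverage_table(pd.concat(rows), layer, cell_area_km2=100.0)
        expected = 100 * layer["fraction_total"].mean()
        assert np.allclose(table["pct_protected"], expected, atol=1e-9)

    def test_fully_protected_region_always_adequate(self):
        rows = [preds(np.full(3000, 0.5), week=w) for w in (20, 21)]
        layer = layer_of(np.ones(3000))
        table = coverage_table(pd.concat(rows), layer, cell_area_km2=100.0)
        assert (table["pct_protected"] == 100.0).all()
        assert table["adequate17"].all() and table["adequate30"].all()

    def test_adequacy_flips_exactly_at_target(self):
        rows = [preds(np.full(3000, 0.5), week=w) for w in (20, 21, 22)]
        layer = layer_of(np.full(3000, 0.25))
        table = coverage_table(pd.concat(rows), layer, cell_area_km2=100.0)
        # range 300,000 km^2 -> targets exactly 17 / 30; coverage 25%
        assert (table["target17"] == 17.0).all()
        assert (table["target30"] == 30.0).all()
        assert table["adequate17"].all()
        assert not table["adequate30"].any()
        assert (table["adequate17"] == (table["pct_protected"] >= table["target17"])).all()

    def test_weeks_outside_window_excluded(self):
        rows = [
            preds(np.full(100, 0.5), week=20),
            preds(np.concatenate([[0.001], np.zeros(99)]), week=40),
        ]
        layer = layer_of(np.full(100, 0.2))
        table = coverage_table(pd.concat(rows), layer, cell_area_km2=100.0)
        assert table["week"].tolist() == [20]
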