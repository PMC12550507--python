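import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from ecometrica import ValidationError, assign_regions, inspect_points, summarize_traits_by_point

from conftest import make_points, make_ranges, make_traits


def brute_force_presence(points, ranges):
    """Per-point species sets by an all-pairs covers() scan (the oracle)."""
    out = []
    for lon, lat in zip(points["lon"], points["lat"]):
        pt = Point(lon, lat)
        out.append(sorted(
            sp for sp, geom in zip(ranges["species"], ranges["geometry"]) if geom.covers(pt)
        ))
    return out


class TestSummarize:
    def test_three_overlapping_squares(self, tiny_overlap):
        ranges, traits = tiny_overlap
        points = make_points([(0.5, 0.5)])
        s = summarize_traits_by_point(points, traits, ranges)
        row = s.iloc[0]
        assert row["richness"] == 3
        assert row["metric1"] == pytest.approx(2.0)
        assert row["metric2"] == pytest.approx(1.0)  # sample SD of {1,2,3}
        assert bool(row["valid"]) is True

    def test_single_species_point_invalid_with_missing_sd(self, tiny_overlap):
        ranges, traits = tiny_overlap
        points = make_points([(-0.15, 0.5)])  # only the third square covers it
        s = summarize_traits_by_point(points, traits, ranges)
        row = s.iloc[0]
        assert row["richness"] == 1
        assert row["metric1"] == pytest.approx(3.0)
        assert np.isnan(row["metric2"])
        assert bool(row["valid"]) is False

    def test_boundary_point_counts_as_present(self):
        ranges = make_ranges([(0, 0, 1, 1)], species=["a"])
        traits = make_traits(["a"], [1.0])
        on_edge = make_points([(1.0, 0.5)])
        s = summarize_traits_by_point(on_edge, traits, ranges)
        assert s["richness"].iloc[0] == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        boxes = []
        for _ in range(20):
            x0, y0 = rng.uniform(-20, 15, 2)
            boxes.append((x0, y0, x0 + rng.uniform(1, 10), y0 + rng.uniform(1, 10)))
        ranges = make_ranges(boxes)
        traits = make_traits(ranges["species"], rng.normal(size=20))
        points = make_points(list(zip(rng.uniform(-20, 20, 50), rng.uniform(-20, 20, 50))))
        s = summarize_traits_by_point(points, traits, ranges)
        expected = brute_force_presence(points, ranges)
        trait_of = dict(zip(traits["species"], traits["trait"]))
        for k, row in s.iterrows():
            assert row["species_present"] == expected[k]
            assert row["richness"] == len(expected[k])
            vals = np.array([trait_of[sp] for sp in expected[k]])
            if len(vals):
                assert row["metric1"] == pytest.approx(vals.mean())
            if len(vals) >= 2:
                assert row["metric2"] == pytest.approx(vals.std(ddof=1))
        # conservation: total richness equals total containment hits
        assert s["richness"].sum() == sum(len(e) for e in expected)

    def test_constant_trait_gives_mean_c_sd_zero(self, tiny_overlap):
        ranges, _ = tiny_overlap
        traits = make_traits(["a", "b", "c"], [7.5, 7.5, 7.5])
        s = summarize_traits_by_point(make_points([(0.5, 0.5)]), traits, ranges)
        assert s["metric1"].iloc[0] == pytest.approx(7.5)
        assert s["metric2"].iloc[0] == pytest.approx(0.0)

    def test_custom_summary_changes_metrics_not_presence(self, tiny_overlap):
        ranges, traits = tiny_overlap
        points = make_points([(0.5, 0.5)])
        default = summarize_traits_by_point(points, traits, ranges)
        custom = summarize_traits_by_point(
            points, traits, ranges, summary_fn_1=max, summary_fn_2=min
        )
        assert custom["species_present"].iloc[0] == default["species_present"].iloc[0]
        assert custom["richness"].iloc[0] == default["richness"].iloc[0]
        assert custom["metric1"].iloc[0] == pytest.approx(3.0)
        assert custom["metric2"].iloc[0] == pytest.approx(1.0)

    def test_rangeonly_species_counts_toward_richness_only(self, tiny_overlap):
        ranges, traits = tiny_overlap
        traits = traits[traits["species"] != "c"]  # c has a range but no trait
        s = summarize_traits_by_point(make_points([(0.5, 0.5)]), traits, ranges)
        row = s.iloc[0]
        assert row["richness"] == 3
        assert row["richness_with_trait"] == 2
        assert row["metric1"] == pytest.approx(1.5)
        assert bool(row["valid"]) is False  # 2 < default threshold 3

    def test_failing_summary_recorded_missing(self, tiny_overlap):
        ranges, traits = tiny_overlap

        def bad(x):
            raise RuntimeError("boom")

        s = summarize_traits_by_point(
            make_points([(0.5, 0.5)]), traits, ranges, summary_fn_1=bad
        )
        assert np.isnan(s["metric1"].iloc[0])
        assert s["metric2"].iloc[0] == pytest.approx(1.0)  # other metric unaffected

    def test_env_columns_carried_through(self, tiny_overlap):
        ranges, traits = tiny_overlap
        points = make_points([(0.5, 0.5)], env=["grassland"], env_col="VegSimple")
        points["elev"] = [120.0]
        s = summarize_traits_by_point(points, traits, ranges)
        assert s["VegSimple"].iloc[0] == "grassland"
        assert s["elev"].iloc[0] == 120.0

    def test_empty_inputs_rejected(self, tiny_overlap):
        ranges, traits = tiny_overlap
        with pytest.raises(ValidationError):
            summarize_traits_by_point(make_points([]), traits, ranges)


class TestAssignRegions:
    def test_label_and_unassigned(self):
        regions = pd.DataFrame(
            {"region": ["NA_box"], "geometry": [box(0, 0, 10, 10)]}
        )
        points = make_points([(5, 5), (20, 20)])
        labels = assign_regions(points, regions)
        assert labels.tolist() == ["NA_box", "unassigned"]

    def test_overlap_first_listed_wins(self):
        regions = pd.DataFrame(
            {"region": ["first", "second"],
             "geometry": [box(0, 0, 10, 10), box(5, 5, 15, 15)]}
        )
        labels = assign_regions(make_points([(7, 7)]), regions)
        assert labels.tolist() == ["first"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        regions = pd.DataFrame(
            {
                "region": [f"r{k}" for k in range(6)],
                "geometry": [
                    box(x0, y0, x0 + 8, y0 + 8)
                    for x0, y0 in zip(rng.uniform(-20, 12, 6), rng.uniform(-20, 12, 6))
                ],
            }
        )
        points = make_points(
            list(zip(rng.uniform(-20, 20, 100), rng.uniform(-20, 20, 100)))
        )
        labels = assign_regions(points, regions)
        for k, (lon, lat) in enumerate(zip(points["lon"], points["lat"])):
            pt = Point(lon, lat)
            hits = [r for r, g in zip(regions["region"], regions["geometry"]) if g.covers(pt)]
            assert labels.iloc[k] == (hits[0] if hits else "unassigned")

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValidationError):
            assign_regions(make_points([(0, 0)]), pd.DataFrame({"region": [], "geometry": []}))


class TestInspectPoints:
    @pytest.fixture
    def summaries(self, tiny_overlap):
        ranges, traits = tiny_overlap
        points = make_points(
            [(0.5, 0.5), (0.3, 0.3), (0.7, 0.7), (-0.15, 0.5), (5.0, 5.0)],
            env=["a", "b", "c", "d", "e"],
            env_col="VegSimple",
        )
        return summarize_traits_by_point(points, traits, ranges)

    def test_explicit_ids_in_given_order(self, summaries):
        report = inspect_points(summaries, point_ids=["p2", "p0", "p3"])
        assert [e["point_id"] for e in report] == ["p2", "p0", "p3"]
        assert all("VegSimple" in e["env"] for e in report)

    def test_unknown_id_is_error(self, summaries):
        with pytest.raises(ValidationError, match="nope"):
            inspect_points(summaries, point_ids=["nope"])

    def test_seeded_selection_reproducible(self, summaries):
        r1 = inspect_points(summaries, n_random=3, seed=7)
        r2 = inspect_points(summaries, n_random=3, seed=7)
        assert [e["point_id"] for e in r1] == [e["point_id"] for e in r2]

    def test_n_random_exceeding_points_reports_all(self, summaries):
        report = inspect_points(summaries, n_random=50, seed=0)
        assert len(report) == len(summaries)

    def test_validity_flag_reflects_threshold(self, summaries):
        report = inspect_points(summaries, point_ids=["p0", "p3"])
        assert report[0]["valid"] is True   # 3 species with traits
        assert report[1]["valid"] is False  # 1 species
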