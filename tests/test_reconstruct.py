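import numpy as np
import pandas as pd
import pytest

from ecometrica import (
    ValidationError,
    fit_categorical,
    fit_continuous,
    haversine_km,
    model_diagnostics,
    nearest_modern_analogue,
    reconstruct_env,
    reconstruct_env_qual,
)
from ecometrica.binning import assign_bin
from ecometrica.reconstruct import EARTH_RADIUS_KM

from conftest import make_points
from test_models import toy_summaries


def fossil_df(rows):
    return pd.DataFrame(rows, columns=["site_id", "lon", "lat", "metric1", "metric2"])


class TestHaversine:
    def test_antipodal_distance_is_pi_r(self):
        d = haversine_km(0.0, 0.0, 180.0, 0.0)
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-6)

    def test_zero_distance_for_identical_points(self):
        assert haversine_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_symmetry(self):
        a = haversine_km(10, 20, -30, 40)
        b = haversine_km(-30, 40, 10, 20)
        assert a == pytest.approx(b)


class TestNearestAnalogue:
    def test_colocated_point_wins_with_zero_distance(self):
        pts = make_points([(0, 0), (10, 10)])
        pid, d = nearest_modern_analogue(10.0, 10.0, pts)
        assert pid == "p1"
        assert d == 0.0

    def test_distance_tie_breaks_lexicographically(self):
        pts = make_points([(1, 0), (-1, 0)])  # equidistant from the origin
        pts["point_id"] = ["zz", "aa"]
        pid, _ = nearest_modern_analogue(0.0, 0.0, pts)
        assert pid == "aa"

    def test_empty_modern_set_rejected(self):
        with pytest.raises(ValidationError):
            nearest_modern_analogue(0.0, 0.0, make_points([]))

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(8)
        pts = make_points(
            list(zip(rng.uniform(-180, 180, 200), rng.uniform(-89, 89, 200)))
        )
        for lon, lat in zip(rng.uniform(-180, 180, 100), rng.uniform(-89, 89, 100)):
            pid, d = nearest_modern_analogue(lon, lat, pts)
            dists = np.array(
                [haversine_km(lon, lat, plon, plat) for plon, plat in zip(pts["lon"], pts["lat"])]
            )
            k = int(np.argmin(dists))
            assert d == pytest.approx(dists[k])
            assert pid == f"p{k}"


class TestReconstructQual:
    @pytest.fixture
    def model(self):
        s = toy_summaries(
            metric1=[0.1, 0.2, 0.7, 0.8, 0.9, 1.0],
            metric2=[0.1, 0.2, 0.1, 0.2, 0.9, 1.0],
            env=["x", "x", "x", "y", "y", "y"],
        )
        return fit_categorical(s, "cat", bins1=2, bins2=2)

    def test_fossil_matching_training_point_gets_its_bin(self, model):
        f = fossil_df([("f1", 0.0, 0.0, 0.1, 0.1)])
        r = reconstruct_env_qual(f, model)
        assert (r["bin_i"].iloc[0], r["bin_j"].iloc[0]) == (0, 0)
        assert r["prediction"].iloc[0] == "x"
        assert not r["imputed_bin"].iloc[0]

    def test_empty_bin_borrows_nearest_nonempty_and_is_flagged(self, model):
        # bin (0,1) is empty; nearest non-empty at index distance 1 are
        # (0,0) and (1,1); the tie goes to smaller i -> (0,0)
        f = fossil_df([("f1", 0.0, 0.0, 0.2, 0.9)])
        r = reconstruct_env_qual(f, model)
        assert r["imputed_bin"].iloc[0]
        assert (r["bin_i"].iloc[0], r["bin_j"].iloc[0]) == (0, 0)
        assert r["prediction"].iloc[0] == "x"

    def test_out_of_range_fossil_clamped_and_flagged(self, model):
        f = fossil_df([("f1", 0.0, 0.0, -5.0, 0.1)])
        r = reconstruct_env_qual(f, model)
        assert r["out_of_range"].iloc[0]
        assert r["bin_i"].iloc[0] == 0

    def test_probability_vector_sums_to_one(self, model):
        f = fossil_df([("f1", 0, 0, 0.75, 0.15), ("f2", 0, 0, 0.2, 0.9)])
        r = reconstruct_env_qual(f, model)
        probs = r[["prob_x", "prob_y"]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)
        # prediction is the argmax of the stored vector
        for _, row in r.iterrows():
            best = "x" if row["prob_x"] >= row["prob_y"] else "y"
            assert row["prediction"] == best

    def test_matches_brute_force_on_random_fossils(self, small_qual_summaries):
        model = fit_categorical(small_qual_summaries, "env", bins1=8, bins2=8)
        rng = np.random.default_rng(9)
        lo1, hi1 = model.grid.edges1[0], model.grid.edges1[-1]
        lo2, hi2 = model.grid.edges2[0], model.grid.edges2[-1]
        f = fossil_df(
            [
                (f"f{k}", 0.0, 0.0, rng.uniform(lo1, hi1), rng.uniform(lo2, hi2))
                for k in range(20)
            ]
        )
        r = reconstruct_env_qual(f, model)
        occ = model.counts.sum(axis=2)
        nonempty = [(i, j) for i in range(occ.shape[0]) for j in range(occ.shape[1]) if occ[i, j]]
        for k, row in r.iterrows():
            i, j, _ = assign_bin(model.grid, f["metric1"][k], f["metric2"][k], clamp=True)
            if occ[i, j] == 0:
                i, j = min(
                    nonempty, key=lambda b: ((b[0] - i) ** 2 + (b[1] - j) ** 2, b[0], b[1])
                )
            assert (row["bin_i"], row["bin_j"]) == (i, j)
            # argmax by enumeration over the bin's counts
            best = max(
                range(len(model.categories)),
                key=lambda c: (model.counts[i, j, c], -c),
            )
            assert row["prediction"] == model.categories[best] or (
                model.counts[i, j].max() == model.counts[i, j, best]
            )

    def test_reconstruction_is_deterministic(self, model):
        f = fossil_df([("f1", 0, 0, 0.5, 0.5), ("f2", 1, 1, 0.9, 0.9)])
        r1 = reconstruct_env_qual(f, model)
        r2 = reconstruct_env_qual(f, model)
        pd.testing.assert_frame_equal(r1, r2)

    def test_training_points_reproduce_training_accuracy(self, small_qual_summaries):
        model = fit_categorical(small_qual_summaries, "env", bins1=8, bins2=8)
        use = small_qual_summaries[
            small_qual_summaries["valid"] & small_qual_summaries["metric2"].notna()
        ]
        f = pd.DataFrame(
            {
                "site_id": use["point_id"].astype(str),
                "lon": use["lon"],
                "lat": use["lat"],
                "metric1": use["metric1"],
                "metric2": use["metric2"],
            }
        )
        r = reconstruct_env_qual(f, model)
        acc = (r["prediction"].to_numpy() == use["env"].to_numpy()).mean()
        assert acc == pytest.approx(model_diagnostics(model)["accuracy"])

    def test_nearest_analogue_fields_present_iff_requested(self, model):
        f = fossil_df([("f1", 0.15, 0.15, 0.1, 0.1)])
        plain = reconstruct_env_qual(f, model)
        assert "nearest_modern_id" not in plain.columns
        pts = make_points([(0.1, 0.1), (50, 50)])
        matched = reconstruct_env_qual(f, model, match_nearest=True, modern_points=pts)
        assert matched["nearest_modern_id"].iloc[0] == "p0"
        assert matched["nearest_modern_distance_km"].iloc[0] >= 0


class TestReconstructCont:
    @pytest.fixture
    def model(self):
        s = toy_summaries(
            metric1=[0.1, 0.2, 0.8, 0.9],
            metric2=[0.1, 0.2, 0.8, 0.9],
            env=[10.0, 12.0, 28.0, 30.0],
            env_col="temp",
        )
        return fit_continuous(s, "temp", bins1=2, bins2=2, env_bins=2)

    def test_single_interval_bin_predicts_its_midpoint(self, model):
        f = fossil_df([("f1", 0, 0, 0.15, 0.15)])
        r = reconstruct_env(f, model)
        assert r["prediction"].iloc[0] == pytest.approx(15.0)  # [10,20) midpoint

    def test_predictions_within_training_env_range(self, cont_world):
        *_, summaries = cont_world
        model = fit_continuous(summaries, "env", bins1=15, bins2=10)
        rng = np.random.default_rng(11)
        lo1, hi1 = model.grid.edges1[0], model.grid.edges1[-1]
        lo2, hi2 = model.grid.edges2[0], model.grid.edges2[-1]
        f = fossil_df(
            [
                (f"f{k}", 0.0, 0.0, rng.uniform(lo1, hi1), rng.uniform(lo2, hi2))
                for k in range(50)
            ]
        )
        r = reconstruct_env(f, model)
        env = model.training["observed"]
        assert (r["prediction"] >= env.min()).all()
        assert (r["prediction"] <= env.max()).all()

    def test_probability_vector_over_env_intervals_sums_to_one(self, model):
        f = fossil_df([("f1", 0, 0, 0.5, 0.5)])
        r = reconstruct_env(f, model)
        probs = r[[c for c in r.columns if c.startswith("prob_env_")]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_non_finite_fossil_metrics_rejected(self, model):
        f = fossil_df([("f1", 0, 0, np.nan, 0.5)])
        with pytest.raises(ValidationError):
            reconstruct_env(f, model)

    def test_model_with_no_occupied_bins_rejected(self, model):
        model.freq = np.zeros_like(model.freq)
        with pytest.raises(ValidationError):
            reconstruct_env(fossil_df([("f1", 0, 0, 0.5, 0.5)]), model)
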