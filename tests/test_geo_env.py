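"""Nitracline interpolation, geography, slopes and index arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plankmap.geo_env import (daily_primary_production, distance_to_coast,
                              haversine_km, index_arithmetic, label_clusters,
                              nearshore_frequency, nitracline_depth,
                              proportion_nearshore, regional_nitracline_slope)


class TestNitracline:
    def test_worked_interpolation(self):
        depth, flag = nitracline_depth([0, 10, 20], [0.0, 0.5, 2.0])
        assert flag == "ok"
        assert depth == pytest.approx(10 + (1 - 0.5) / (2 - 0.5) * 10, abs=1e-9)
        assert depth == pytest.approx(13.33, abs=0.01)

    def test_surface_already_at_threshold(self):
        depth, flag = nitracline_depth([5, 15, 30], [5.0, 8.0, 12.0])
        assert (depth, flag) == (5.0, "ok")

    def test_threshold_never_reached(self):
        depth, flag = nitracline_depth([0, 10, 20], [0.1, 0.4, 0.8])
        assert np.isnan(depth)
        assert flag == "deeper-than-profile"

    def test_insufficient_points(self):
        depth, flag = nitracline_depth([10], [2.0])
        assert np.isnan(depth)
        assert flag == "insufficient"
        depth, flag = nitracline_depth([0, 10], [np.nan, 2.0])
        assert flag == "insufficient"

    @given(st.lists(st.floats(0.0, 30.0), min_size=3, max_size=10),
           st.floats(0.5, 5.0), st.floats(0.1, 3.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold_and_in_range(self, raw, t_lo, dt):
        no3 = np.sort(np.asarray(raw))
        depths = np.arange(len(no3), dtype=float) * 10.0
        d_lo, f_lo = nitracline_depth(depths, no3, threshold=t_lo)
        d_hi, f_hi = nitracline_depth(depths, no3, threshold=t_lo + dt)
        for d, f in ((d_lo, f_lo), (d_hi, f_hi)):
            if f == "ok":
                assert depths[0] <= d <= depths[-1]
        if f_lo == "ok" and f_hi == "ok":
            assert d_lo <= d_hi + 1e-9


class TestDistanceToCoast:
    coast = np.array([[-117.0, 0.0], [-117.0, 1.0], [-117.0, 2.0]])

    def test_on_vertex_is_zero(self):
        d = distance_to_coast({"lon": -117.0, "lat": 1.0,
                               "distance_to_coast_km": None}, self.coast)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_at_equator(self):
        d = distance_to_coast({"lon": -118.0, "lat": 0.0,
                               "distance_to_coast_km": None}, self.coast)
        assert d == pytest.approx(111.19, abs=0.01)

    def test_metadata_takes_precedence(self):
        d = distance_to_coast({"lon": -130.0, "lat": 0.0,
                               "distance_to_coast_km": 42.0}, self.coast)
        assert d == 42.0

    def test_no_source_errors(self):
        with pytest.raises(ValueError):
            distance_to_coast({"lon": 0.0, "lat": 0.0,
                               "distance_to_coast_km": None}, None)

    def test_haversine_symmetry(self):
        assert haversine_km(-117, 33, -120, 35) == pytest.approx(
            haversine_km(-120, 35, -117, 33))


def _geo_fixture():
    stations = pd.DataFrame({
        "station_id": ["near", "far"], "lon": [-117.2, -120.0],
        "lat": [33.8, 32.5], "distance_to_coast_km": [8.0, 300.0],
        "is_cardinal": [True, True]})
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "station_id": ["near"] * 4 + ["far"] * 4,
        "cruise_id": ["c1", "c1", "c2", "c2"] * 2})
    cls = pd.DataFrame({
        "sample_id": samples["sample_id"], "group": "all",
        "bmu": 0, "cluster": [1, 1, 1, 2, 2, 2, 2, 2]})
    return stations, samples, cls


class TestLabelClusters:
    def test_coastal_cluster_labeled_nearshore(self):
        stations, samples, cls = _geo_fixture()
        geo = label_clusters(cls, samples, stations)
        labels = geo.set_index("cluster")["label"]
        assert labels[1] == "nearshore"
        assert labels[2] == "offshore"
        assert set(cls["label"]) == {"nearshore", "offshore"}

    def test_equal_weights_centroid_is_midpoint(self):
        stations = pd.DataFrame({
            "station_id": ["A", "B", "C"], "lon": [-117.0, -118.0, -120.0],
            "lat": [34.0, 33.0, 32.0], "distance_to_coast_km": [10.0, 100.0, 300.0],
            "is_cardinal": True})
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "station_id": ["A", "A", "B", "B", "C", "C"],
            "cruise_id": "c1"})
        # cluster 1 at half of A's and half of B's samples, absent at C
        cls = pd.DataFrame({"sample_id": samples["sample_id"], "group": "all",
                            "bmu": 0, "cluster": [1, 2, 1, 2, 2, 2]})
        geo = label_clusters(cls, samples, stations).set_index("cluster")
        assert geo.loc[1, "centroid_lon"] == pytest.approx(np.mean([-117.0, -118.0]))
        assert geo.loc[1, "centroid_lat"] == pytest.approx(np.mean([34.0, 33.0]))
        assert geo.loc[1, "label"] == "nearshore"

    def test_relabeling_swap_maps_to_label_swap(self):
        stations, samples, cls = _geo_fixture()
        geo = label_clusters(cls.copy(), samples, stations)
        swapped = cls.copy()
        swapped["cluster"] = swapped["cluster"].map({1: 2, 2: 1})
        geo_swapped = label_clusters(swapped, samples, stations)
        a = geo.set_index("label")["centroid_distance_km"]
        b = geo_swapped.set_index("label")["centroid_distance_km"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_centroid_tie_demands_manual_label(self):
        stations, samples, cls = _geo_fixture()
        stations["distance_to_coast_km"] = 50.0
        cls["cluster"] = [1, 2] * 4
        with pytest.raises(ValueError, match="tie"):
            label_clusters(cls, samples, stations)

    def test_nearshore_frequency_counts(self):
        stations, samples, cls = _geo_fixture()
        label_clusters(cls, samples, stations)
        freq = nearshore_frequency(cls, samples).set_index("station_id")
        assert freq.loc["near", "successes"] == 3
        assert freq.loc["near", "trials"] == 4
        assert freq.loc["far", "frequency"] == pytest.approx(0.0)


class TestRegionalSlope:
    def test_exact_line_recovered(self):
        x = np.array([10.0, 50.0, 120.0, 300.0])
        nit = pd.DataFrame({"station_id": [f"st{i}" for i in range(4)],
                            "cruise_id": "c1",
                            "nitracline_m": 0.2 * x + 5.0})
        stations = pd.DataFrame({"station_id": [f"st{i}" for i in range(4)],
                                 "distance_to_coast_km": x})
        cs = regional_nitracline_slope(nit, stations, "c1")
        assert cs.slope == pytest.approx(0.2, abs=1e-12)
        assert cs.intercept == pytest.approx(5.0, abs=1e-10)
        assert cs.slope_se == pytest.approx(0.0, abs=1e-10)

    def test_constant_nitracline_flat(self):
        nit = pd.DataFrame({"station_id": ["a", "b", "c"], "cruise_id": "c1",
                            "nitracline_m": [30.0, 30.0, 30.0]})
        stations = pd.DataFrame({"station_id": ["a", "b", "c"],
                                 "distance_to_coast_km": [5.0, 50.0, 200.0]})
        assert regional_nitracline_slope(nit, stations, "c1").slope == pytest.approx(0.0)

    def test_too_few_stations_flagged(self):
        nit = pd.DataFrame({"station_id": ["a", "b"], "cruise_id": "c1",
                            "nitracline_m": [10.0, np.nan]})
        stations = pd.DataFrame({"station_id": ["a", "b"],
                                 "distance_to_coast_km": [5.0, 50.0]})
        cs = regional_nitracline_slope(nit, stations, "c1")
        assert cs.flag == "insufficient-stations"
        assert np.isnan(cs.slope)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(3, 12)
            x = rng.uniform(0, 300, n)
            y = rng.normal(0.2 * x + 8, 3)
            nit = pd.DataFrame({"station_id": [f"s{i}" for i in range(n)],
                                "cruise_id": "c", "nitracline_m": y})
            stations = pd.DataFrame({"station_id": [f"s{i}" for i in range(n)],
                                     "distance_to_coast_km": x})
            cs = regional_nitracline_slope(nit, stations, "c")
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert cs.intercept == pytest.approx(beta[0], abs=1e-10)
            assert cs.slope == pytest.approx(beta[1], abs=1e-10)


class TestProportionAndIndices:
    def test_all_nearshore_is_one(self):
        _, samples, cls = _geo_fixture()
        cls["label"] = "nearshore"
        out = proportion_nearshore(cls, samples).set_index("cruise_id")
        assert (out["proportion_nearshore"] == 1.0).all()

    def test_swap_invariance_of_proportions(self):
        stations, samples, cls = _geo_fixture()
        label_clusters(cls, samples, stations)
        p1 = proportion_nearshore(cls, samples)
        swapped = cls.drop(columns="label").copy()
        swapped["cluster"] = swapped["cluster"].map({1: 2, 2: 1})
        label_clusters(swapped, samples, stations)
        p2 = proportion_nearshore(swapped, samples)
        pd.testing.assert_frame_equal(p1, p2)

    def test_regional_nitrate_and_guard(self):
        idx = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=3, freq="MS"),
                            "cuti": [1.0, 0.0, 2.0], "beuti": [2.0, 5.0, 1.0]})
        out = index_arithmetic(idx)
        assert out.loc[0, "regional_nitrate"] == pytest.approx(2.0)
        assert np.isnan(out.loc[1, "regional_nitrate"])
        assert out.loc[2, "regional_nitrate"] == pytest.approx(0.5)

    def test_moving_average_identity_on_constant(self):
        idx = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=12, freq="MS"),
                            "cuti": 1.5, "beuti": 3.0})
        out = index_arithmetic(idx)
        np.testing.assert_allclose(out["cuti_smooth"], 1.5)
        np.testing.assert_allclose(out["regional_nitrate_smooth"], 2.0)

    def test_daily_primary_production(self):
        out = daily_primary_production([3.0], [1, 2, 3, 4, 5, 6])
        assert out["daily"][0] == pytest.approx(6.0)
        assert out["integrated"] == pytest.approx(3.5)
        six_equal = daily_primary_production([0.0], [7.0] * 6)
        assert six_equal["integrated"] == pytest.approx(7.0)
        with pytest.warns(UserWarning, match="6 light levels"):
            daily_primary_production([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            daily_primary_production([-1.0])
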