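import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import migflow as mf
from migflow.migration import ODMatrix
from oracles import lp_wasserstein


def od(counts: dict, index, columns) -> ODMatrix:
    frame = pd.DataFrame(0.0, index=index, columns=columns)
    for (i, j), v in counts.items():
        frame.loc[i, j] = v
    return ODMatrix(counts=frame)


class TestODDifference:
    def test_identical_matrices_give_zero(self):
        a = od({("X", "Z"): 5, ("X", "W"): 5}, ["X"], ["Z", "W"])
        diff = mf.od_difference(a, a)
        assert np.allclose(diff.to_numpy(), 0.0)

    def test_doubling_counts_leaves_percentages_unchanged(self):
        a = od({("X", "Z"): 3, ("X", "W"): 1, ("Y", "Z"): 2, ("Y", "W"): 2},
               ["X", "Y"], ["Z", "W"])
        b = ODMatrix(counts=a.counts * 2)
        assert np.allclose(mf.od_difference(a, b).to_numpy(), 0.0)
        raw = mf.od_difference(a, b, as_percentage=False)
        assert raw.loc["X", "Z"] == 3

    def test_mass_shift_moves_percentage_points(self):
        a = od({("X", "Z"): 50, ("X", "W"): 50}, ["X"], ["Z", "W"])
        b = od({("X", "Z"): 40, ("X", "W"): 60}, ["X"], ["Z", "W"])
        diff = mf.od_difference(a, b)
        assert diff.loc["X", "Z"] == pytest.approx(-10.0)
        assert diff.loc["X", "W"] == pytest.approx(10.0)

    def test_empty_origin_row_is_missing(self):
        a = od({("X", "Z"): 5}, ["X", "Y"], ["Z"])
        diff = mf.od_difference(a, a)
        assert np.isnan(diff.loc["Y", "Z"])


class TestZScoreFilter:
    def test_extreme_cell_retains_its_destination(self):
        frame = pd.DataFrame(np.zeros((3, 3)), index=list("xyz"),
                             columns=list("abc"))
        frame.loc["x", "b"] = 10.0
        kept = mf.zscore_filter_destinations(frame)
        assert kept == ["b"]

    def test_constant_matrix_retains_nothing(self):
        frame = pd.DataFrame(np.ones((3, 3)))
        with pytest.warns(UserWarning):
            assert mf.zscore_filter_destinations(frame) == []

    def test_matches_hand_standardisation_on_fixture(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 2, (4, 4))
        frame = pd.DataFrame(vals, index=list("wxyz"), columns=list("abcd"))
        z = (vals - vals.mean()) / vals.std(ddof=1)
        want = [c for j, c in enumerate(frame.columns)
                if (z[:, j] > 1.96).any()]
        assert mf.zscore_filter_destinations(frame) == want

    def test_per_origin_mode(self):
        frame = pd.DataFrame([[0.0] * 7 + [10.0],
                              [1.0] * 8],
                             index=["x", "y"], columns=list("abcdefgh"))
        kept = mf.zscore_filter_destinations(frame, mode="per_origin")
        assert kept == ["h"]


class TestWasserstein:
    def coords(self, xs):
        return pd.Series(xs, index=[f"d{i}" for i in range(len(xs))])

    def series(self, ws):
        return pd.Series(ws, index=[f"d{i}" for i in range(len(ws))])

    def test_identical_distributions_have_zero_divergence(self):
        p = self.series([0.3, 0.7])
        assert mf.wasserstein_divergence(p, p, self.coords([1.0, 4.0])) == 0.0

    def test_point_mass_translation(self):
        p = self.series([1.0, 0.0])
        q = self.series([0.0, 1.0])
        assert mf.wasserstein_divergence(p, q, self.coords([2.0, 5.0])) == \
            pytest.approx(3.0)

    def test_half_split_against_lp_oracle(self):
        p = self.series([0.5, 0.5])
        q = self.series([1.0, 0.0])
        got = mf.wasserstein_divergence(p, q, self.coords([1.0, 3.0]))
        assert got == pytest.approx(1.0)
        assert got == pytest.approx(lp_wasserstein(
            np.array([0.5, 0.5]), np.array([1.0, 0.0]),
            np.array([1.0, 3.0])), abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 6), st.integers(0, 2 ** 31 - 1))
    def test_matches_lp_oracle_and_metric_axioms(self, n, seed):
        rng = np.random.default_rng(seed)
        xs = np.sort(rng.uniform(0, 10, n))
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        r = rng.dirichlet(np.ones(n))
        coords = self.coords(xs)
        d_pq = mf.wasserstein_divergence(self.series(p), self.series(q), coords)
        assert d_pq == pytest.approx(lp_wasserstein(p, q, xs), abs=1e-9)
        assert d_pq >= 0
        d_qp = mf.wasserstein_divergence(self.series(q), self.series(p), coords)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        d_pr = mf.wasserstein_divergence(self.series(p), self.series(r), coords)
        d_rq = mf.wasserstein_divergence(self.series(r), self.series(q), coords)
        assert d_pq <= d_pr + d_rq + 1e-9

    def test_mismatched_support_rejected(self):
        with pytest.raises(mf.ValidationError):
            mf.wasserstein_divergence(self.series([1.0, 0.0]),
                                      pd.Series([1.0], index=["other"]),
                                      self.coords([0.0, 1.0]))


class TestDeltaRurality:
    def test_hand_computed_weighted_mean(self, tiny_geo):
        m = od({("X", "Z"): 10, ("X", "W"): 30}, ["X"], ["Z", "W"])
        change = mf.delta_rurality(m, m, tiny_geo.comunas, "X")
        # (10*0.2 + 30*0.6) / 40 = 0.5
        assert change.r_year == pytest.approx(0.5)
        assert change.delta == pytest.approx(0.0)

    def test_scale_invariance_of_yearly_term(self, tiny_geo):
        a = od({("X", "Z"): 10, ("X", "W"): 30}, ["X"], ["Z", "W"])
        b = ODMatrix(counts=a.counts * 7)
        change = mf.delta_rurality(b, a, tiny_geo.comunas, "X")
        assert change.delta == pytest.approx(0.0, abs=1e-12)

    def test_fully_rural_destinations_bound(self, tiny_geo):
        com = tiny_geo.comunas.copy()
        com["rural_fraction"] = 1.0
        m = od({("X", "Z"): 3, ("X", "W"): 9}, ["X"], ["Z", "W"])
        change = mf.delta_rurality(m, m, com, "X")
        assert change.r_year == pytest.approx(1.0)

    def test_no_emigrants_gives_missing(self, tiny_geo):
        empty = od({}, ["X"], ["Z", "W"])
        m = od({("X", "Z"): 1}, ["X"], ["Z", "W"])
        change = mf.delta_rurality(m, empty, tiny_geo.comunas, "X")
        assert np.isnan(change.r_baseline)


class TestWeightedAttribute:
    def test_equal_weights_average_density(self, tiny_geo):
        com = tiny_geo.comunas.copy()
        com.loc[com["comuna_id"] == "Z", ["population", "area_km2"]] = [1000, 10]
        com.loc[com["comuna_id"] == "W", ["population", "area_km2"]] = [3000, 10]
        com["density"] = com["population"] / com["area_km2"]
        m = od({("X", "Z"): 5, ("X", "W"): 5}, ["X"], ["Z", "W"])
        got = mf.weighted_destination_attribute(m, com, "X", "density")
        assert got.value == pytest.approx(200.0)
        assert got.coverage == pytest.approx(1.0)

    def test_icvu_weighted_difference(self, tiny_geo):
        com = tiny_geo.comunas.copy()
        com.loc[com["comuna_id"] == "Z", "icvu"] = 70.0
        com.loc[com["comuna_id"] == "W", "icvu"] = 60.0
        m = od({("X", "Z"): 75, ("X", "W"): 25}, ["X"], ["Z", "W"])
        got = mf.weighted_destination_attribute(m, com, "X", "icvu")
        # weighted mean of (70-80, 60-80) with weights .75/.25 -> -12.5
        assert got.value == pytest.approx(-12.5)

    def test_icvu_missing_destination_renormalises_and_reports_coverage(
            self, tiny_geo):
        m = od({("X", "Z"): 60, ("X", "W"): 40}, ["X"], ["Z", "W"])
        got = mf.weighted_destination_attribute(m, tiny_geo.comunas, "X", "icvu")
        assert got.value == pytest.approx(70.0 - 80.0)  # W has no icvu
        assert got.coverage == pytest.approx(0.6)

    def test_single_destination_returns_its_attribute(self, tiny_geo):
        m = od({("X", "W"): 4}, ["X"], ["W"])
        got = mf.weighted_destination_attribute(m, tiny_geo.comunas, "X",
                                                "rural_fraction")
        assert got.value == pytest.approx(0.6)


class TestGravity:
    def test_score_and_ordering(self):
        regions = pd.DataFrame({
            "region_id": ["F", "A", "B"],
            "name": ["f", "a", "b"],
            "population": [5000, 1000, 1000],
            "distance_to_origin_km": [0.0, 10.0, 20.0],
        })
        ranked = mf.gravity_rank(regions)
        assert list(ranked["region_id"]) == ["A", "B"]
        assert ranked["gravity"].iloc[0] == pytest.approx(100.0)

    def test_five_region_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pops = rng.integers(1000, 100000, 5)
        dists = rng.uniform(10, 2000, 5)
        regions = pd.DataFrame({
            "region_id": [f"R{i}" for i in range(5)],
            "name": [f"r{i}" for i in range(5)],
            "population": pops, "distance_to_origin_km": dists})
        regions.loc[5] = ["F", "f", 999, 0.0]
        want = sorted(range(5), key=lambda i: -pops[i] / dists[i])
        got = [int(r[1]) for r in mf.gravity_rank(regions)["region_id"]]
        assert got == want

    def test_zero_distance_nonfocal_rejected(self):
        regions = pd.DataFrame({
            "region_id": ["F", "A"], "name": ["f", "a"],
            "population": [1, 1], "distance_to_origin_km": [0.0, -1.0]})
        with pytest.raises(mf.ValidationError):
            mf.gravity_rank(regions)


class TestHostImpact:
    def test_percentage_of_host_population(self, tiny_geo):
        a = od({("X", "Z"): 650}, ["X"], ["Z"])
        b = od({("X", "Z"): 1300}, ["X"], ["Z"])
        regions = tiny_geo.regions.copy()
        regions.loc[regions["region_id"] == "RB", "population"] = 100000
        got = mf.host_region_impact(a, b, tiny_geo.comunas, regions, "RA")
        row = got[got["region_id"] == "RB"].iloc[0]
        assert row["pct_year_b"] == pytest.approx(1.3)
        assert row["pct_year_a"] == pytest.approx(0.65)
        assert row["difference"] == pytest.approx(0.65)

    def test_zero_arrivals_and_linearity(self, tiny_geo):
        empty = od({}, ["X"], ["Z"])
        b = od({("X", "Z"): 40}, ["X"], ["Z"])
        got = mf.host_region_impact(empty, b, tiny_geo.comunas,
                                    tiny_geo.regions, "RA")
        row = got[got["region_id"] == "RB"].iloc[0]
        assert row["pct_year_a"] == 0.0
        b2 = ODMatrix(counts=b.counts * 2)
        got2 = mf.host_region_impact(empty, b2, tiny_geo.comunas,
                                     tiny_geo.regions, "RA")
        assert got2[got2["region_id"] == "RB"]["pct_year_b"].iloc[0] == \
            pytest.approx(2 * row["pct_year_b"])


class TestDecileBinnedOD:
    def test_single_flow_fills_one_cell(self, tiny_geo):
        m = od({("Y", "Z"): 4}, ["Y"], ["Z"])  # decile 3 -> decile 6
        mat = mf.decile_binned_od(m, tiny_geo.comunas)
        assert mat.loc[6, 3] == pytest.approx(1.0)
        assert mat.to_numpy().sum() == pytest.approx(1.0)

    def test_columns_normalise_to_one(self, tiny_geo):
        m = od({("X", "Z"): 2, ("X", "W"): 6, ("Y", "W"): 5},
               ["X", "Y"], ["Z", "W"])
        with pytest.warns(UserWarning):
            mat = mf.decile_binned_od(m, tiny_geo.comunas)
        sums = mat.sum(axis=0)
        nonempty = sums[sums > 0]
        assert np.allclose(nonempty.to_numpy(), 1.0, atol=1e-12)

    def test_three_flow_fixture_matches_hand_tabulation(self, tiny_geo):
        m = od({("X", "Z"): 2, ("X", "W"): 6, ("Y", "Z"): 5},
               ["X", "Y"], ["Z", "W"])
        with pytest.warns(UserWarning):
            mat = mf.decile_binned_od(m, tiny_geo.comunas)
        # origin X (decile 9): 2 to decile 6, 6 to decile 2
        assert mat.loc[6, 9] == pytest.approx(0.25)
        assert mat.loc[2, 9] == pytest.approx(0.75)
        # origin Y (decile 3): all to decile 6
        assert mat.loc[6, 3] == pytest.approx(1.0)


def test_emigration_submatrix_restricts_to_boundary_flows(tiny_geo):
    counts = pd.DataFrame(1, index=["X", "Y", "Z"], columns=["X", "Z", "W"])
    emi = mf.emigration_submatrix(ODMatrix(counts=counts),
                                  tiny_geo.comunas, "RA")
    assert list(emi.counts.index) == ["X", "Y"]
    assert list(emi.counts.columns) == ["Z", "W"]


def test_divergence_lower_for_broader_stable_destination_sets(tiny_geo):
    """Origins that keep their destination mix show less divergence."""
    a = od({("X", "Z"): 5, ("X", "W"): 5, ("Y", "Z"): 5, ("Y", "W"): 5},
           ["X", "Y"], ["Z", "W"])
    b = od({("X", "Z"): 5, ("X", "W"): 5, ("Y", "Z"): 10, ("Y", "W"): 0},
           ["X", "Y"], ["Z", "W"])
    div = mf.divergences_by_origin(a, b, tiny_geo.comunas)
    assert div["X"] == pytest.approx(0.0)
    assert div["Y"] > div["X"]
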