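import datetime as dt

import numpy as np
import pandas as pd
import pytest

import migflow as mf
from conftest import events_frame

START = dt.date(2020, 3, 1)
END = dt.date(2020, 3, 31)


class TestCountTransitions:
    def test_same_comuna_pair_is_internal(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T10:00:00", "Xa"),
                           ("d1", "2020-03-02T11:00:00", "Xa"),
                           ("d1", "2020-03-02T12:00:00", "Xb")])
        tr = mf.count_transitions(ev, tiny_geo.antennas)
        assert len(tr) == 1
        assert bool(tr["internal"].iloc[0])

    def test_out_and_back_gives_two_external(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T10:00:00", "Xa"),
                           ("d1", "2020-03-02T11:00:00", "Za"),
                           ("d1", "2020-03-02T12:00:00", "Xa")])
        tr = mf.count_transitions(ev, tiny_geo.antennas)
        assert len(tr) == 2
        assert (~tr["internal"]).all()

    def test_single_ping_and_repeats_emit_nothing(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T10:00:00", "Xa"),
                           ("d2", "2020-03-02T10:00:00", "Za"),
                           ("d2", "2020-03-02T11:00:00", "Za")])
        assert mf.count_transitions(ev, tiny_geo.antennas).empty

    def test_no_cross_device_transitions(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T10:00:00", "Xa"),
                           ("d2", "2020-03-02T11:00:00", "Za")])
        assert mf.count_transitions(ev, tiny_geo.antennas).empty

    def test_midnight_span_attributed_to_second_event(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T23:50:00", "Xa"),
                           ("d1", "2020-03-03T00:10:00", "Za")])
        tr = mf.count_transitions(ev, tiny_geo.antennas)
        assert tr["date"].iloc[0] == pd.Timestamp("2020-03-03")

    def test_unknown_antenna_rejected(self, tiny_geo):
        ev = events_frame([("d1", "2020-03-02T10:00:00", "??")])
        with pytest.raises(mf.ValidationError):
            mf.count_transitions(ev, tiny_geo.antennas)


def _index_for(rows, tiny_geo, homes, **kwargs):
    ev = events_frame(rows)
    tr = mf.count_transitions(ev, tiny_geo.antennas)
    active = mf.daily_active(ev)
    return mf.mobility_index(tr, homes, active, **kwargs)


class TestMobilityIndex:
    def test_per_device_mean(self, tiny_geo):
        homes = pd.DataFrame({"device_id": ["d1", "d2"],
                              "home_comuna_id": ["X", "X"]})
        rows = []
        # d1: 3 transitions, d2: 5, all on 2020-03-02 within comuna X
        for d, n in (("d1", 3), ("d2", 5)):
            ants = ["Xa", "Xb"] * 3
            for i in range(n + 1):
                rows.append((d, f"2020-03-02T{10 + i}:00:00", ants[i % 2]))
        out = _index_for(rows, tiny_geo, homes)
        row = out[(out["comuna_id"] == "X")
                  & (out["date"] == pd.Timestamp("2020-03-02"))].iloc[0]
        assert row["total"] == pytest.approx(4.0)
        assert row["internal"] == pytest.approx(4.0)
        assert row["external"] == pytest.approx(0.0)

    def test_active_device_without_transitions_counts_in_denominator(
            self, tiny_geo):
        homes = pd.DataFrame({"device_id": ["d1", "d2"],
                              "home_comuna_id": ["X", "X"]})
        rows = [("d1", "2020-03-02T10:00:00", "Xa"),
                ("d1", "2020-03-02T11:00:00", "Xb"),
                ("d2", "2020-03-02T10:30:00", "Xa")]
        out = _index_for(rows, tiny_geo, homes)
        row = out[out["date"] == pd.Timestamp("2020-03-02")].iloc[0]
        assert row["total"] == pytest.approx(0.5)

    def test_day_without_active_devices_is_missing(self, tiny_geo):
        homes = pd.DataFrame({"device_id": ["d1"], "home_comuna_id": ["X"]})
        rows = [("d1", "2020-03-02T10:00:00", "Xa")]
        out = _index_for(rows, tiny_geo, homes,
                         study_start=dt.date(2020, 3, 1),
                         study_end=dt.date(2020, 3, 3))
        empty_day = out[out["date"] == pd.Timestamp("2020-03-03")].iloc[0]
        assert np.isnan(empty_day["total"])

    def test_additivity_internal_plus_external(self, small_scenario,
                                               small_homes):
        cfg = small_scenario.ground_truth.config
        ev = small_scenario.events
        sub = ev[ev["device_id"].isin(ev["device_id"].unique()[:200])]
        base = mf.baseline_homes(small_homes, cfg.baseline_week,
                                 small_scenario.geography.comunas)
        tr = mf.count_transitions(sub, small_scenario.geography.antennas)
        out = mf.mobility_index(tr, base, mf.daily_active(sub))
        ok = out.dropna(subset=["total"])
        assert np.allclose(ok["internal"] + ok["external"], ok["total"])


class TestReduction:
    def make_series(self, values, comuna="X"):
        dates = pd.date_range("2020-03-02", periods=len(values), freq="D")
        return pd.DataFrame({"comuna_id": comuna, "date": dates,
                             "n_active": 1, "internal": 0.0,
                             "external": values, "total": values})

    def test_arithmetic(self):
        # baseline week 2020-03-09..15 -> mean 10; later day at 8 -> 20pp
        vals = [10.0] * 14 + [8.0, 10.0, 0.0]
        series = self.make_series(vals)
        out = mf.reduction_vs_baseline(series, 1, dt.date(2020, 3, 1))
        by_date = out.set_index("date")
        assert by_date.loc["2020-03-16", "reduction_total_pp"] == \
            pytest.approx(20.0)
        assert by_date.loc["2020-03-17", "reduction_total_pp"] == \
            pytest.approx(0.0)
        assert by_date.loc["2020-03-18", "reduction_total_pp"] == \
            pytest.approx(100.0)

    def test_baseline_week_reductions_average_to_zero(self):
        rng = np.random.default_rng(4)
        vals = list(rng.uniform(5, 15, 30))
        out = mf.reduction_vs_baseline(self.make_series(vals), 1,
                                       dt.date(2020, 3, 1))
        week = out[out["date"].isin(mf.weeks.week_dates(1, dt.date(2020, 3, 1)))]
        assert week["reduction_total_pp"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_zero_baseline_reported_missing(self):
        vals = [0.0] * 20
        with pytest.warns(UserWarning):
            out = mf.reduction_vs_baseline(self.make_series(vals), 1,
                                           dt.date(2020, 3, 1))
        assert out["reduction_total_pp"].isna().all()


class TestQuarantineStratification:
    def cal(self):
        return mf.QuarantineCalendar.from_intervals(pd.DataFrame({
            "comuna_id": ["X"], "start_date": ["2020-03-10"],
            "end_date": ["2020-03-20"]}))

    def test_partition_of_study_days(self):
        dates = pd.date_range("2020-03-01", "2020-03-31", freq="D")
        series = pd.DataFrame({"comuna_id": "X", "date": dates, "total": 1.0})
        out = mf.stratify_by_quarantine(series, self.cal())
        assert out["in_quarantine"].sum() == 10
        assert (~out["in_quarantine"]).sum() == 21

    def test_never_quarantined_comuna_has_empty_stratum(self):
        dates = pd.date_range("2020-03-01", "2020-03-05", freq="D")
        series = pd.DataFrame({"comuna_id": "Y", "date": dates, "total": 1.0})
        out = mf.stratify_by_quarantine(series, self.cal())
        assert not out["in_quarantine"].any()

    def test_full_period_quarantine_has_empty_complement(self):
        dates = pd.date_range("2020-03-10", "2020-03-19", freq="D")
        series = pd.DataFrame({"comuna_id": "X", "date": dates, "total": 1.0})
        out = mf.stratify_by_quarantine(series, self.cal())
        assert out["in_quarantine"].all()


def test_planted_reduction_recovered_on_scenario():
    """Post-shock mean reduction per decile tracks the planted gradient."""
    cfg = mf.ScenarioConfig(
        n_devices=4000, rng_seed=23, noise_fraction=0.0,
        migration_fraction=0.0, study_end=dt.date(2020, 5, 31),
        mobility_shock_date=dt.date(2020, 3, 16))
    sc = mf.simulate_scenario(cfg)
    geo = sc.geography
    homes = mf.weekly_homes(sc.events, geo.antennas, cfg.study_start,
                            cfg.study_end)
    base = mf.baseline_homes(homes, cfg.baseline_week, geo.comunas)
    series = mf.compute_mobility(sc.events, geo.antennas, base,
                                 cfg.study_start, cfg.study_end,
                                 cfg.baseline_week)
    post = series[series["date"] >= pd.Timestamp(cfg.mobility_shock_date)]
    dec = geo.comunas.set_index("comuna_id")["income_decile"] \
        .round().clip(1, 10).astype(int)
    post = post.assign(decile=dec.reindex(post["comuna_id"]).to_numpy())
    # pooled index per decile per day, then reduction vs pooled baseline
    pooled = post.groupby(["decile", "date"]).apply(
        lambda g: (g["total"] * g["n_active"]).sum()
        / max(g["n_active"].sum(), 1), include_groups=False)
    recovered = {}
    basew = series[series["date"].isin(
        mf.weeks.week_dates(cfg.baseline_week, cfg.study_start))]
    basew = basew.assign(decile=dec.reindex(basew["comuna_id"]).to_numpy())
    base_pooled = basew.groupby("decile").apply(
        lambda g: (g["total"] * g["n_active"]).sum()
        / max(g["n_active"].sum(), 1), include_groups=False)
    for d in pooled.index.get_level_values(0).unique():
        recovered[d] = 100 * (1 - pooled[d].mean() / base_pooled[d])
    planted = {d: 100 * r for d, r in
               cfg.mobility_reduction_by_decile.items()}
    diffs = [recovered[d] - planted[d] for d in recovered]
    assert max(abs(x) for x in diffs) < 8.0  # sampling noise at 4k devices
    rs = np.corrcoef([planted[d] for d in recovered],
                     [recovered[d] for d in recovered])[0, 1]
    assert rs > 0.9
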