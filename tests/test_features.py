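"""Daily feature computations against hand/geometry oracles."""

import numpy as np
import pytest

from gpsmobility.features import (HomeLocation, circadian_routine_series,
                                  compute_daily_features, daily_feature_table,
                                  find_significant_locations, infer_home,
                                  location_entropy)

from .conftest import day_trace, flight, pause

DAY = 86400.0
H = 3600.0


def home_at(x=0.0, y=0.0):
    return HomeLocation("T00", x, y)


class TestSignificantLocations:
    def test_single_point_gives_single_location(self):
        traces = [day_trace(0, [pause(0, DAY, 10.0, -5.0)])]
        locs = find_significant_locations(traces)
        assert len(locs) == 1
        assert locs[0].x == pytest.approx(10.0)
        assert locs[0].y == pytest.approx(-5.0)

    def test_two_clusters_1km_apart_found_at_weighted_centroids(self):
        rng = np.random.default_rng(0)
        traces = []
        for d in range(4):
            segs = []
            t = d * DAY
            for i in range(6):
                dx, dy = rng.normal(0, 20, 2)
                segs.append(pause(t, t + H, dx, dy))
                t += H
                dx, dy = rng.normal(0, 20, 2)
                segs.append(pause(t, t + H, 1000.0 + dx, dy))
                t += H
            traces.append(day_trace(d, segs))
        locs = find_significant_locations(traces, seed=3)
        assert len(locs) == 2
        xs = sorted(l.x for l in locs)
        assert xs[0] == pytest.approx(0.0, abs=30.0)
        assert xs[1] == pytest.approx(1000.0, abs=30.0)

    def test_clusters_closer_than_merge_radius_are_merged(self):
        traces = []
        for d in range(4):
            traces.append(day_trace(d, [
                pause(d * DAY, d * DAY + 6 * H, 0.0, 0.0),
                pause(d * DAY + 7 * H, d * DAY + 13 * H, 300.0, 0.0),
            ]))
        locs = find_significant_locations(traces, seed=1)
        assert len(locs) == 1
        assert 0.0 <= locs[0].x <= 300.0

    def test_short_pauses_do_not_qualify(self):
        traces = [day_trace(0, [pause(0, 300, 0.0, 0.0)])]  # 5 min < 10 min
        with pytest.warns(UserWarning, match="no qualifying pauses"):
            assert find_significant_locations(traces) == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        traces = [day_trace(0, [pause(i * H, (i + 1) * H,
                                      *rng.normal(0, 3000, 2))
                                for i in range(20)])]
        a = find_significant_locations(traces, seed=9)
        b = find_significant_locations(traces, seed=9)
        assert [(l.x, l.y, l.total_pause_minutes) for l in a] == \
            [(l.x, l.y, l.total_pause_minutes) for l in b]


class TestInferHome:
    def test_single_location_is_home(self):
        traces = [day_trace(0, [pause(0, DAY, 7.0, 7.0)])]
        locs = find_significant_locations(traces)
        h = infer_home(locs, traces)
        assert (h.x, h.y) == (locs[0].x, locs[0].y)

    def test_night_occupancy_wins(self):
        # A occupied 22:00-06:00 nightly; B occupied 10:00-16:00
        traces = []
        for d in range(3):
            t = d * DAY
            traces.append(day_trace(d, [
                pause(t, t + 6 * H, 0.0, 0.0),            # A overnight
                pause(t + 10 * H, t + 16 * H, 5000.0, 0.0),  # B daytime
                pause(t + 22 * H, t + 24 * H, 0.0, 0.0),   # A evening
            ]))
        locs = find_significant_locations(traces)
        h = infer_home(locs, traces)
        assert abs(h.x) < 1.0

    def test_larger_night_minutes_win(self):
        # A: 300 night-min/day (21:00-02:00), B: 200 night-min/day (01:00-...)
        traces = []
        for d in range(3):
            t = d * DAY
            traces.append(day_trace(d, [
                pause(t + 21 * H, t + 26 * H, 0.0, 0.0),          # A 300 min
                pause(t + 2 * H, t + 5 * H + 20 * 60, 5000.0, 0.0),  # B 200 min
            ]))
        locs = find_significant_locations(traces)
        h = infer_home(locs, traces)
        assert abs(h.x) < 1.0


class TestDailyFeatures:
    def test_all_day_home_pause(self):
        tr = day_trace(0, [pause(0, DAY, 0.0, 0.0)])
        locs = find_significant_locations([tr])
        f = compute_daily_features(tr, home_at(), locs)
        assert f["distance_traveled"] == 0.0
        assert f["radius_of_gyration"] == 0.0
        assert f["max_diameter"] == 0.0
        assert f["max_distance_home"] == 0.0
        assert f["home_time"] == 1440.0
        assert f["probability_paused"] == 1.0
        assert f["avg_flight_length"] == 0.0

    def test_symmetric_two_pause_day(self):
        # equal time paused at (0,0) and (100,0), negligible flight time
        tr = day_trace(0, [pause(0, 12 * H, 0.0, 0.0),
                           flight(12 * H, 12 * H + 1, 0, 0, 100, 0),
                           pause(12 * H + 1, 24 * H + 1, 100.0, 0.0)])
        f = compute_daily_features(tr, home_at(), [])
        assert f["radius_of_gyration"] == pytest.approx(50.0, rel=1e-3)
        assert f["max_diameter"] == pytest.approx(100.0)

    def test_flight_arithmetic(self):
        tr = day_trace(0, [pause(0, 10 * H, 0.0, 0.0),
                           flight(10 * H, 10 * H + 200, 0, 0, 400, 0),
                           pause(10 * H + 200, 12 * H, 400.0, 0.0),
                           flight(12 * H, 12 * H + 400, 400, 0, 400, 600),
                           pause(12 * H + 400, 24 * H, 400.0, 600.0)])
        f = compute_daily_features(tr, home_at(), [])
        assert f["distance_traveled"] == pytest.approx(1000.0)
        assert f["avg_flight_length"] == pytest.approx(500.0)
        assert f["avg_flight_duration"] == pytest.approx(300.0)

    def test_max_distance_home_zero_when_all_pauses_near_home(self):
        tr = day_trace(0, [pause(0, DAY, 150.0, 0.0)])
        f = compute_daily_features(tr, home_at(), [])
        assert f["max_distance_home"] == 0.0

    def test_translation_invariance(self):
        segs = [pause(0, 10 * H, 0.0, 0.0),
                flight(10 * H, 10 * H + 600, 0, 0, 2000, 0),
                pause(10 * H + 600, DAY, 2000.0, 0.0)]
        tr = day_trace(0, segs)
        shifted = day_trace(0, [type(s)(s.kind, s.start, s.end,
                                        s.x0 + 7e4, s.y0 - 3e4,
                                        s.x1 + 7e4, s.y1 - 3e4, s.imputed)
                                for s in segs])
        f1 = compute_daily_features(tr, home_at(0, 0), [])
        f2 = compute_daily_features(shifted, home_at(7e4, -3e4), [])
        for k in ("distance_traveled", "radius_of_gyration", "max_diameter",
                  "max_distance_home", "home_time", "probability_paused"):
            assert f2[k] == pytest.approx(f1[k], rel=1e-9, abs=1e-6)


class TestLocationEntropy:
    def loc(self, x, y, label=0):
        from gpsmobility.features import SignificantLocation
        return SignificantLocation(label, x, y, 100.0)

    def test_single_location(self):
        tr = day_trace(0, [pause(0, DAY, 0.0, 0.0)])
        ent, n = location_entropy(tr, [self.loc(0, 0)])
        assert ent == 0.0 and n == 1

    def test_even_split_two_locations(self):
        tr = day_trace(0, [pause(0, 12 * H, 0.0, 0.0),
                           pause(12 * H, DAY, 1000.0, 0.0)])
        ent, n = location_entropy(tr, [self.loc(0, 0), self.loc(1000, 0, 1)])
        assert ent == pytest.approx(np.log(2), abs=1e-9)
        assert n == 2

    def test_uneven_split_hand_value(self):
        # shares 0.7 / 0.2 / 0.1 -> -sum(p ln p) = 0.8018 nats
        tr = day_trace(0, [pause(0, 7 * H, 0.0, 0.0),
                           pause(7 * H, 9 * H, 1000.0, 0.0),
                           pause(9 * H, 10 * H, 2000.0, 0.0)])
        locs = [self.loc(0, 0), self.loc(1000, 0, 1), self.loc(2000, 0, 2)]
        ent, n = location_entropy(tr, locs)
        expected = -(0.7 * np.log(0.7) + 0.2 * np.log(0.2) + 0.1 * np.log(0.1))
        assert ent == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8018, abs=5e-4)
        assert n == 3

    def test_no_pause_near_any_location(self):
        tr = day_trace(0, [pause(0, DAY, 9000.0, 9000.0)])
        ent, n = location_entropy(tr, [self.loc(0, 0)])
        assert ent == 0.0 and n == 0

    def test_entropy_bounded_by_log_visited(self):
        rng = np.random.default_rng(7)
        locs = [self.loc(2000 * i, 0, i) for i in range(4)]
        for _ in range(20):
            k = int(rng.integers(1, 5))
            bounds = np.sort(rng.uniform(0, 24, k - 1)) if k > 1 else np.array([])
            edges = np.concatenate([[0.0], bounds, [24.0]])
            segs = [pause(edges[i] * H, edges[i + 1] * H, 2000.0 * i, 0.0)
                    for i in range(k) if edges[i + 1] > edges[i]]
            ent, n = location_entropy(day_trace(0, segs), locs)
            assert ent <= np.log(max(n, 1)) + 1e-9


class TestCircadianRoutine:
    def test_identical_days_give_one(self):
        traces = [day_trace(d, [pause(d * DAY, d * DAY + 9 * H, 0.0, 0.0),
                                pause(d * DAY + 9 * H, (d + 1) * DAY,
                                      1000.0, 0.0)])
                  for d in range(5)]
        r = circadian_routine_series(traces)
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_distinct_locations_every_day_give_zero(self):
        traces = [day_trace(d, [pause(d * DAY, (d + 1) * DAY, 3000.0 * d, 0.0)])
                  for d in range(5)]
        r = circadian_routine_series(traces)
        assert all(v == pytest.approx(0.0) for v in r.values())

    def test_half_matching_day_gives_half(self):
        # day 1 equals day 0 for the first 12 h, is >200 m away after
        t0 = [pause(0, 12 * H, 0.0, 0.0), pause(12 * H, DAY, 1000.0, 0.0)]
        t1 = [pause(DAY, DAY + 12 * H, 0.0, 0.0),
              pause(DAY + 12 * H, 2 * DAY, 5000.0, 0.0)]
        r = circadian_routine_series([day_trace(0, t0), day_trace(1, t1)])
        assert r[0] == pytest.approx(0.5)
        assert r[1] == pytest.approx(0.5)

    def test_weekend_stratification(self):
        # study starts Monday 2023-05-01; weekdays at x=0, weekends at x=5000
        traces = []
        for d in range(14):
            x = 5000.0 if (d % 7) in (5, 6) else 0.0
            traces.append(day_trace(d, [pause(d * DAY, (d + 1) * DAY, x, 0.0)]))
        plain = circadian_routine_series(traces, stratified=False)
        strat = circadian_routine_series(traces, stratified=True)
        # unstratified: weekdays match 9 of 13 other days
        assert plain[0] == pytest.approx(9 / 13)
        # stratified: all comparison days identical
        assert all(v == pytest.approx(1.0) for v in strat.values())

    def test_single_day_has_no_comparison(self):
        traces = [day_trace(0, [pause(0, DAY, 0.0, 0.0)])]
        r = circadian_routine_series(traces)
        assert np.isnan(r[0])


class TestFeatureTable:
    def test_feature_category_coherence_on_cohort(self, small_cohort):
        """Activity features intercorrelate positively; activity and home
        time are negatively related across participant-days."""
        cfg, streams, _, _ = small_cohort
        from gpsmobility.pipeline import PipelineParams, extract_daily_features
        daily, _ = extract_daily_features(
            streams, PipelineParams(seed=0, study_days=cfg.study_days))
        d = daily.dropna(subset=["distance_traveled", "home_time"])
        c = d[["distance_traveled", "radius_of_gyration", "max_diameter",
               "home_time"]].corr()
        assert c.loc["distance_traveled", "radius_of_gyration"] > 0.3
        assert c.loc["distance_traveled", "max_diameter"] > 0.3
        assert c.loc["distance_traveled", "home_time"] < -0.2
        # bounded features stay in range
        assert daily["probability_paused"].dropna().between(0, 1).all()
        assert daily["circadian_routine"].dropna().between(0, 1).all()
        ent = daily.dropna(subset=["sig_location_entropy"])
        ok = ent["sig_locations_visited"] >= 1
        assert (ent.loc[ok, "sig_location_entropy"]
                <= np.log(ent.loc[ok, "sig_locations_visited"].clip(lower=1))
                + 1e-9).all()

    def test_excluded_days_get_nan_features(self):
        traces = [day_trace(d, [pause(d * DAY, (d + 1) * DAY, 0.0, 0.0)])
                  for d in range(4)]
        traces[2].excluded = True
        df = daily_feature_table(traces)
        assert np.isnan(df.loc[2, "distance_traveled"])
        assert df.loc[2, "excluded"]
        assert df.loc[1, "home_time"] == 1440.0
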