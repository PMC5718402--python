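"""First passage time: closed forms, brute-force oracles, scale selection."""

import numpy as np
import pandas as pd
import pytest

from sealforage import fpt as fp
from sealforage import geo
from sealforage.config import SimConfig
from sealforage.synthetic import simulate_track
from tests.conftest import straight_track


def brute_force_fpt(points, r_km):
    """Independent step-by-step crossing search (the oracle)."""
    lon = points.lon.to_numpy()
    lat = points.lat.to_numpy()
    t_hr = points.time.values.astype("datetime64[ns]").astype("int64") \
        / 1e9 / 3600.0
    n = len(points)
    out = np.full(n, np.nan)
    for i in range(n):
        t_exit = None
        for j in range(i + 1, n):
            dj = geo.haversine_km(lon[j], lat[j], lon[i], lat[i])
            if dj > r_km:
                dprev = geo.haversine_km(lon[j - 1], lat[j - 1],
                                         lon[i], lat[i])
                f = (r_km - dprev) / (dj - dprev)
                t_exit = t_hr[j - 1] + f * (t_hr[j] - t_hr[j - 1])
                break
        if t_exit is None:
            continue
        t_entry = None
        for j in range(i - 1, -1, -1):
            dj = geo.haversine_km(lon[j], lat[j], lon[i], lat[i])
            if dj > r_km:
                dnext = geo.haversine_km(lon[j + 1], lat[j + 1],
                                         lon[i], lat[i])
                f = (dj - r_km) / (dj - dnext)
                t_entry = t_hr[j] + f * (t_hr[j + 1] - t_hr[j])
                break
        if t_entry is None:
            continue
        out[i] = t_exit - t_entry
    return out


def random_walk_points(rng, n=50, lat0=70.0):
    lons, lats = [0.0], [lat0]
    for _ in range(n - 1):
        lo, la = geo.destination(lons[-1], lats[-1],
                                 rng.uniform(0, 360), rng.uniform(2, 12))
        lons.append(lo)
        lats.append(la)
    t = pd.date_range("2008-04-01", periods=n, freq="1h")
    return pd.DataFrame({"animal_id": "a", "time": t, "lon": lons,
                         "lat": lats})


class TestResample:
    def test_straight_100km_gives_21_points(self):
        # 100 km at 5 km spacing -> 21 points including both endpoints
        tr = straight_track(n=11, speed_ms=10 / 3.6 * 1000 / 3600)
        # build explicitly: 10 segments of 10 km
        rows = [(0.0, 70.0)]
        for _ in range(10):
            rows.append(geo.destination(rows[-1][0], rows[-1][1], 90.0, 10.0))
        df = pd.DataFrame({"animal_id": "a",
                           "time": pd.date_range("2008-04-01", periods=11,
                                                 freq="1h"),
                           "lon": [r[0] for r in rows],
                           "lat": [r[1] for r in rows]})
        out = fp.resample_track_equidistant(df, 5.0)
        assert len(out) == 21

    def test_path_length_preserved(self, rng):
        # gently turning track: 5-km chords track the path to < 0.1%
        rows = [(0.0, 70.0)]
        brg = 90.0
        for _ in range(30):
            brg += rng.uniform(-10, 10)
            rows.append(geo.destination(rows[-1][0], rows[-1][1], brg,
                                        rng.uniform(15, 40)))
        pts = pd.DataFrame({"animal_id": "a",
                            "time": pd.date_range("2008-04-01",
                                                  periods=len(rows),
                                                  freq="1h"),
                            "lon": [r[0] for r in rows],
                            "lat": [r[1] for r in rows]})
        out = fp.resample_track_equidistant(pts, 5.0)
        lon, lat = out.lon.to_numpy(), out.lat.to_numpy()
        resampled_len = geo.haversine_km(lon[:-1], lat[:-1],
                                         lon[1:], lat[1:]).sum()
        lon0, lat0 = pts.lon.to_numpy(), pts.lat.to_numpy()
        orig_len = geo.haversine_km(lon0[:-1], lat0[:-1],
                                    lon0[1:], lat0[1:]).sum()
        covered = np.floor(orig_len / 5.0) * 5.0   # span of the resampling
        assert resampled_len == pytest.approx(covered, rel=1e-3)

    def test_constant_speed_gives_regular_timestamps(self):
        tr = straight_track(n=30, speed_ms=1.5)
        out = fp.resample_track_equidistant(tr, 5.0)
        dt = np.diff(out.time.values.astype("int64")) / 1e9
        assert np.allclose(dt, dt[0], rtol=1e-6)

    def test_short_trip_single_point(self):
        tr = straight_track(n=2, speed_ms=0.1)
        out = fp.resample_track_equidistant(tr, 5.0)
        assert len(out) == 1


class TestFptValues:
    def test_straight_track_closed_form(self):
        v = 1.0  # m/s
        tr = straight_track(n=200, speed_ms=v, dt_hr=1.0)
        pts = fp.resample_track_equidistant(tr, 5.0)
        for r in (10.0, 30.0):
            vals = fp.fpt_at_radius(pts, r)
            expected_hr = 2 * r * 1000 / v / 3600.0
            interior = vals[np.isfinite(vals)]
            assert len(interior) > 10
            assert np.allclose(interior, expected_hr, rtol=0.02)

    def test_doubling_back_exceeds_straight_fpt(self):
        # out 40 km, back 20, out 60: the mid points dwell inside r=30
        rows = [(0.0, 70.0)]
        for brg, dist in [(90, 10)] * 4 + [(270, 10)] * 2 + [(90, 10)] * 6:
            rows.append(geo.destination(rows[-1][0], rows[-1][1], brg, dist))
        df = pd.DataFrame({"animal_id": "a",
                           "time": pd.date_range("2008-04-01",
                                                 periods=len(rows), freq="1h"),
                           "lon": [r[0] for r in rows],
                           "lat": [r[1] for r in rows]})
        vals = fp.fpt_at_radius(df, 30.0)
        straight_expected = 6.0   # 60 km at 10 km/hr
        assert np.nanmax(vals) > straight_expected

    def test_matches_brute_force_oracle(self, rng):
        pts = random_walk_points(rng, 50)
        for r in (5.0, 15.0, 40.0):
            fast = fp.fpt_at_radius(pts, r)
            slow = brute_force_fpt(pts, r)
            assert np.allclose(np.isnan(fast), np.isnan(slow))
            m = np.isfinite(fast)
            assert np.allclose(fast[m], slow[m], rtol=1e-9)

    def test_nonnegative_radius_rejected(self):
        tr = straight_track(n=5)
        with pytest.raises(ValueError):
            fp.fpt_at_radius(tr, 0.0)

    def test_monotone_in_radius(self, rng):
        pts = random_walk_points(rng, 60)
        a = fp.fpt_at_radius(pts, 10.0)
        b = fp.fpt_at_radius(pts, 20.0)
        m = np.isfinite(a) & np.isfinite(b)
        assert (b[m] - a[m] > -1e-9).all()

    def test_invariant_to_track_reversal(self, rng):
        pts = random_walk_points(rng, 50)
        rev = pts.iloc[::-1].reset_index(drop=True).copy()
        t0 = pts.time.iloc[0]
        span = pts.time.iloc[-1] - pts.time.iloc[0]
        rev["time"] = [t0 + (span - (t - t0)) for t in rev.time][::1]
        rev = rev.sort_values("time").reset_index(drop=True)
        a = fp.fpt_at_radius(pts, 20.0)
        b = fp.fpt_at_radius(rev, 20.0)
        m = np.isfinite(a)
        assert np.allclose(a[m], b[::-1][m], rtol=1e-9)


class TestScaleSelection:
    def test_selection_invariant_to_trip_order(self, rng):
        trips = [random_walk_points(rng, 40) for _ in range(3)]
        radii = np.arange(5, 51, 5.0)
        s1, _ = fp.select_ars_scale(trips, radii)
        s2, _ = fp.select_ars_scale(trips[::-1], radii)
        assert s1 == s2

    def test_flat_curve_flagged_non_informative(self, caplog):
        tr = straight_track(n=300, speed_ms=1.5)
        pts = fp.resample_track_equidistant(tr, 5.0)
        with caplog.at_level("WARNING", logger="sealforage.fpt"):
            fp.select_ars_scale([pts], np.arange(5, 31, 5.0))
        assert any("non-informative" in r.message for r in caplog.records)

    def test_patch_track_recovers_patch_scale(self):
        cfg = SimConfig(n_animals=1, class_mix=(0, 1, 0), duration_days=25,
                        patch_centers=((20.0, 71.5),), patch_radius_km=30.0,
                        argos_error_sd_by_lc={k: 0.0 for k in "3210AB"},
                        lc_probs={"3": 1.0}, n_spike_fixes=0, seed=12)
        _, truth = simulate_track(cfg)
        tr = truth.latent_track
        tr = tr[tr["mode"] != "haulout"]
        pts = fp.resample_track_equidistant(tr, 5.0)
        sel, _ = fp.select_ars_scale([pts], np.arange(5, 101, 5.0))
        assert 15.0 <= sel <= 50.0

    def test_fpt_higher_inside_patches(self):
        cfg = SimConfig(n_animals=1, class_mix=(0, 1, 0), duration_days=25,
                        patch_centers=((20.0, 71.5),), patch_radius_km=30.0,
                        argos_error_sd_by_lc={k: 0.0 for k in "3210AB"},
                        lc_probs={"3": 1.0}, n_spike_fixes=0, seed=13)
        _, truth = simulate_track(cfg)
        tr = truth.latent_track[truth.latent_track["mode"] != "haulout"]
        pts = fp.resample_track_equidistant(tr, 5.0)
        vals = fp.fpt_at_radius(pts, 30.0)
        d = geo.haversine_km(pts.lon.to_numpy(), pts.lat.to_numpy(),
                             20.0, 71.5)
        inside = vals[(d <= 30.0) & np.isfinite(vals)]
        outside = vals[(d > 60.0) & np.isfinite(vals)]
        assert inside.mean() > outside.mean()


class TestHauloutExclusionAndDaily:
    def _fpt_points(self, rng, n=50):
        pts = random_walk_points(rng, n)
        pts["fpt_hr"] = rng.uniform(1, 20, n)
        return pts

    def test_no_haulouts_identity(self, rng):
        pts = self._fpt_points(rng)
        out = fp.exclude_haulout_fpt(pts, None, pd.DataFrame(), 30.0)
        assert len(out) == len(pts)

    def test_all_points_at_haulout_site_removed(self, rng):
        pts = self._fpt_points(rng, 10)
        pts["lon"] = 5.0
        pts["lat"] = 70.0
        hp = pd.DataFrame({"animal_id": ["a"], "lon": [5.0], "lat": [70.0]})
        out = fp.exclude_haulout_fpt(pts, None, hp, 30.0)
        assert len(out) == 0

    def test_removed_count_matches_distance_oracle(self, rng):
        pts = self._fpt_points(rng, 50)
        hp = pd.DataFrame({"animal_id": ["a"], "lon": [0.5], "lat": [70.2]})
        out = fp.exclude_haulout_fpt(pts, None, hp, 25.0)
        expected_removed = sum(
            geo.haversine_km(r.lon, r.lat, 0.5, 70.2) <= 25.0
            for r in pts.itertuples())
        assert len(pts) - len(out) == expected_removed

    def test_daily_fpt_constant_day(self):
        t = pd.date_range("2008-04-01", periods=8, freq="3h")
        pts = pd.DataFrame({"animal_id": "a", "time": t, "lon": 0.0,
                            "lat": 70.0, "fpt_hr": 6.0})
        out = fp.daily_fpt(pts)
        assert len(out) == 1
        assert out.daily_fpt_hr.iloc[0] == pytest.approx(6.0)

    def test_daily_fpt_groupby_oracle(self, rng):
        n = 60
        t = pd.Timestamp("2008-04-01") + pd.to_timedelta(
            rng.uniform(0, 5 * 24, n), unit="h")
        pts = pd.DataFrame({"animal_id": rng.choice(["a", "b"], n),
                            "time": t, "lon": 0.0, "lat": 70.0,
                            "fpt_hr": rng.uniform(1, 30, n)})
        out = fp.daily_fpt(pts)
        acc = {}
        for r in pts.itertuples():
            acc.setdefault((r.animal_id, r.time.date()), []).append(r.fpt_hr)
        assert len(out) == len(acc)
        for r in out.itertuples():
            assert r.daily_fpt_hr == pytest.approx(
                float(np.mean(acc[(r.animal_id, r.day.date())])))

    def test_days_without_points_absent(self):
        t = pd.to_datetime(["2008-04-01 02:00", "2008-04-03 05:00"])
        pts = pd.DataFrame({"animal_id": "a", "time": t, "lon": 0.0,
                            "lat": 70.0, "fpt_hr": [5.0, 7.0]})
        out = fp.daily_fpt(pts)
        assert len(out) == 2
        assert pd.Timestamp("2008-04-02") not in set(out.day)


class TestForagingDays:
    def _daily(self, values):
        return pd.DataFrame({
            "animal_id": "a",
            "day": pd.date_range("2008-04-01", periods=len(values)),
            "daily_fpt_hr": values})

    def test_1_to_100_flags_exactly_25(self):
        out = fp.foraging_days(self._daily(np.arange(1.0, 101.0)))
        assert int(out.foraging.sum()) == 25

    def test_all_equal_flags_none(self):
        out = fp.foraging_days(self._daily(np.full(20, 5.0)))
        assert not out.foraging.any()

    def test_flagged_set_matches_sort_threshold_oracle(self, rng):
        vals = rng.uniform(0, 50, 40)
        out = fp.foraging_days(self._daily(vals))
        thr = np.quantile(vals, 0.75)   # numpy default = type 7
        assert set(out[out.foraging].day) == set(
            out[out.daily_fpt_hr > thr].day)

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            fp.foraging_days(self._daily([1.0, 2.0, 3.0]))
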