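import numpy as np
import pandas as pd
import pytest

import predspace as ps
from predspace.screening import (
    STATUS_MOVING,
    STATUS_REMOVED_ELEV,
    STATUS_REMOVED_SPEED,
    STATUS_REMOVED_WINDOW,
    STATUS_RESTING,
    _RETAINED,
)


def make_track(xy, start="2014-05-01T00:00:00", interval_h=2.0,
               elevation=500.0, species="dingo", release=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    times = pd.date_range(start, periods=n, freq=pd.Timedelta(hours=interval_h))
    elev = np.full(n, elevation) if np.isscalar(elevation) else elevation
    return ps.Track(
        animal_id="t1", species=species, sex="M",
        fixes=pd.DataFrame({"animal_id": "t1", "timestamp": times,
                            "x": xy[:, 0], "y": xy[:, 1],
                            "elevation": elev}),
        release_time=None if release is None else pd.Timestamp(release),
    )


class TestClipWindow:
    def test_within_24h_of_release_removed(self):
        tr = make_track([(0, 0)] * 20, start="2014-05-01T00:00:00",
                        release="2014-04-30T12:00:00")
        params = ps.ScreeningParams.for_species(
            "dingo", window_end=pd.Timestamp("2014-07-06"))
        out = ps.clip_window(tr, params)
        # first fixes fall within 24 h of release (cut at 2014-05-01T12:00)
        early = out.fixes[out.fixes.timestamp < "2014-05-01T12:00:00"]
        assert (early.status == STATUS_REMOVED_WINDOW).all()

    def test_fix_at_or_after_window_end_removed(self):
        end = pd.Timestamp("2014-05-01T06:00:00")
        tr = make_track([(0, 0)] * 5)
        params = ps.ScreeningParams.for_species("dingo", window_end=end)
        out = ps.clip_window(tr, params)
        after = out.fixes[out.fixes.timestamp >= end]
        assert len(after) > 0
        assert (after.status == STATUS_REMOVED_WINDOW).all()

    def test_interval_membership_oracle(self):
        rng = np.random.default_rng(0)
        n = 100
        t0 = pd.Timestamp("2014-04-01")
        times = t0 + pd.to_timedelta(
            np.sort(rng.uniform(0, 120 * 24, n)), unit="h")
        tr = ps.Track(
            animal_id="t1", species="dingo", sex="M",
            fixes=pd.DataFrame({"timestamp": times, "x": 0.0, "y": 0.0,
                                "elevation": 500.0}),
            release_time=t0 + pd.Timedelta(days=2),
        )
        end = t0 + pd.Timedelta(days=100)
        params = ps.ScreeningParams.for_species("dingo", window_end=end)
        out = ps.clip_window(tr, params)
        start = max(end - pd.Timedelta(days=70),
                    tr.release_time + pd.Timedelta(hours=24))
        expect = (out.fixes.timestamp >= start) & (out.fixes.timestamp < end)
        got = out.fixes.status.isin(_RETAINED)
        assert (expect == got).all()


class TestSpeedFilter:
    def test_gallop_violation_removed(self):
        # 34 km in 2 h = 17 km/h > 16 km/h dingo gallop
        tr = make_track([(0, 0), (34_000, 0), (34_000, 100)])
        out = ps.speed_filter(tr, ps.ScreeningParams.for_species("dingo"))
        assert out.fixes.status.iloc[1] == STATUS_REMOVED_SPEED
        assert out.fixes.status.iloc[2] != STATUS_REMOVED_SPEED

    def test_below_trot_both_sides_retained(self):
        # 16 km in 2 h = 8.0 km/h on both sides: below the 8.75 trot ceiling
        tr = make_track([(0, 0), (16_000, 0), (32_000, 0)])
        out = ps.speed_filter(tr, ps.ScreeningParams.for_species("dingo"))
        assert (out.fixes.status.isin(_RETAINED)).all()

    def test_sustained_trot_removed(self):
        # 9 km/h into and out of the middle fix (> 8.75) but < gallop
        tr = make_track([(0, 0), (18_000, 0), (36_000, 0), (36_100, 0)])
        out = ps.speed_filter(tr, ps.ScreeningParams.for_species("dingo"))
        assert out.fixes.status.iloc[1] == STATUS_REMOVED_SPEED

    def test_injected_spikes_removed_exactly(self, lmap, dingo_population):
        tracks, truth = dingo_population
        params = ps.ScreeningParams.for_species("dingo")
        for tr, rec in zip(tracks, truth["animals"]):
            out = ps.speed_filter(tr, params)
            removed = np.flatnonzero(out.fixes.status == STATUS_REMOVED_SPEED)
            assert sorted(removed) == sorted(rec["spike_indices"])
            # post-condition: no retained consecutive pair above gallop
            kept = out.fixes[out.fixes.status.isin(_RETAINED)]
            d = np.hypot(np.diff(kept.x), np.diff(kept.y)) / 1000
            dt = np.diff(kept.timestamp.to_numpy().astype(
                "datetime64[s]").astype(float)) / 3600
            assert np.all(d / dt <= params.gallop_kmh + 1e-9)


class TestElevationFilter:
    def test_paper_tolerance(self):
        tr = make_track([(0, 0), (10, 0), (20, 0)],
                        elevation=np.array([500.0, 650.0, 599.9]))
        out = ps.elevation_filter(tr, 500.0,
                                  ps.ScreeningParams.for_species("dingo"))
        assert out.fixes.status.iloc[1] == STATUS_REMOVED_ELEV
        assert out.fixes.status.iloc[2] in _RETAINED

    def test_absolute_difference_oracle(self):
        rng = np.random.default_rng(3)
        elev = rng.normal(500, 80, 200)
        tr = make_track([(i, 0) for i in range(200)], elevation=elev)
        out = ps.elevation_filter(tr, 500.0,
                                  ps.ScreeningParams.for_species("dingo"))
        expect = np.abs(elev - 500.0) > 100.0
        got = (out.fixes.status == STATUS_REMOVED_ELEV).to_numpy()
        assert (expect == got).all()

    def test_missing_elevation_retained(self):
        tr = make_track([(0, 0), (5, 0)],
                        elevation=np.array([500.0, np.nan]))
        out = ps.elevation_filter(tr, 500.0,
                                  ps.ScreeningParams.for_species("dingo"))
        assert out.fixes.status.iloc[1] in _RETAINED
        assert out.log["n_missing_elev"] == 1


class TestClassifyMovement:
    def test_cat_thresholds_strict(self):
        tr = make_track([(0, 0), (36, 0), (36, 35.0)], interval_h=4.0,
                        species="cat")
        out = ps.classify_movement(tr, ps.ScreeningParams.for_species("cat"))
        assert out.fixes.status.iloc[1] == STATUS_MOVING  # 36 m > 35
        assert out.fixes.status.iloc[2] == STATUS_RESTING  # exactly 35 m

    def test_simulator_truth(self, lmap):
        cfg = ps.SimAnimalConfig.for_species("cat", n_steps=150,
                                             rest_prob=0.3, spike_rate=0.0)
        tr, truth = ps.simulate_track(lmap, cfg, seed=17)
        out = ps.classify_movement(
            tr, ps.ScreeningParams.for_species("cat"))
        resting = np.flatnonzero(out.fixes.status == STATUS_RESTING)
        # first fix has no predecessor and is resting by convention
        assert set(resting) == set(truth["rest_indices"]) | {0}


class TestBuildSteps:
    def _moving_track(self, xy, interval_h=2.0):
        tr = make_track(xy, interval_h=interval_h)
        return ps.classify_movement(
            tr, ps.ScreeningParams.for_species("dingo"))

    def test_collinear_turn_angle_zero(self):
        tr = self._moving_track([(0, 0), (100, 0), (200, 0), (300, 0)])
        steps = ps.build_steps(tr)
        turns = [s.turn_rad for s in steps if s.turn_rad is not None]
        assert turns and all(t == pytest.approx(0.0) for t in turns)

    def test_gap_breaks_steps(self):
        times = pd.to_datetime([
            "2014-04-30T22:00", "2014-05-01T00:00", "2014-05-01T02:00",
            "2014-05-01T08:00", "2014-05-01T10:00",  # 3-interval gap before
        ])
        df = pd.DataFrame({"timestamp": times,
                           "x": [-100.0, 0.0, 100.0, 200.0, 300.0],
                           "y": 0.0, "elevation": 500.0})
        tr = ps.Track("t1", "dingo", "M", df)
        tr = ps.classify_movement(tr, ps.ScreeningParams.for_species("dingo"))
        steps = ps.build_steps(tr)
        spans = {(s.start_time.hour, s.end_time.hour) for s in steps}
        assert spans == {(0, 2), (8, 10)}  # nothing spans the gap

    def test_step_count_matches_interval_scan_oracle(self, dingo_population):
        tracks, _ = dingo_population
        params = ps.ScreeningParams.for_species("dingo")
        for tr in tracks:
            scr = ps.screen_track(tr, params, ref_elev=500.0)
            steps = ps.build_steps(scr)
            mv = scr.moving
            dt = np.diff(mv.timestamp.to_numpy().astype(
                "datetime64[s]").astype(float)) / 3600
            expect = int(np.sum(np.abs(dt - 2.0) <= 0.25))
            assert len(steps) == expect


class TestScreenPipeline:
    def test_idempotence(self, dingo_population):
        tracks, _ = dingo_population
        params = ps.ScreeningParams.for_species("dingo")
        once = ps.screen_track(tracks[0], params, ref_elev=500.0)
        twice = ps.screen_track(once, params, ref_elev=500.0)
        assert (once.fixes.status == twice.fixes.status).all()

    def test_clean_simulation_all_moving(self, lmap):
        cfg = ps.SimAnimalConfig.for_species("dingo", n_steps=80,
                                             rest_prob=0.0, spike_rate=0.0,
                                             elev_noise_m=5.0)
        tr, _ = ps.simulate_track(lmap, cfg, seed=23)
        out = ps.screen_track(tr, ps.ScreeningParams.for_species("dingo"),
                              ref_elev=500.0)
        status = out.fixes.status
        assert not status.str.startswith("removed").any()
        # everything but the first (no-predecessor) fix is moving
        assert (status.iloc[1:] == STATUS_MOVING).all()
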