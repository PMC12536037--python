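import numpy as np
import pandas as pd
import pytest
import shapely

from pmexposure.config import ContextParams
from pmexposure.context import (
    StudyArea,
    classify_trip_mode,
    context_accuracy,
    detect_stays_trips,
    filter_valid_days,
    identify_context,
    impute_gps,
    moving_median,
    Segment,
    smooth_gps,
)
from pmexposure.geo import LocalProjection
from oracles import oracle_stay_windows, random_track


# ---------------------------------------------------------------------------
# smoothing / imputation


class TestSmoothing:
    def test_constant_track_unchanged(self):
        x = np.full(20, 5.0)
        assert np.array_equal(moving_median(x, 5), x)

    def test_spike_replaced_by_neighbour_median(self):
        # 500 m spike at index 4 in an otherwise stationary window-5 track
        x = np.array([0.0, 0.0, 0.0, 0.0, 500.0, 0.0, 0.0, 0.0])
        sm = moving_median(x, 5)
        # hand-computed: median of {0,0,500,0,0} = 0
        assert sm[4] == 0.0
        assert np.array_equal(sm[:3], x[:3])

    def test_single_fix_unchanged(self):
        assert moving_median(np.array([7.0]), 5)[0] == 7.0

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            moving_median(np.arange(5.0), 4)
        with pytest.raises(ValueError):
            moving_median(np.arange(5.0), 1)

    def test_gaps_preserved_through_smoothing(self):
        x = np.array([0.0, np.nan, 2.0, 3.0, np.nan, 5.0])
        y = x.copy()
        sx, sy = smooth_gps(x, y, 3)
        assert np.isnan(sx[1]) and np.isnan(sx[4])


class TestImputation:
    def test_short_gap_filled_on_straight_path(self):
        t = np.arange(10)
        x = t * 10.0
        y = t * 5.0
        x[[3, 4, 5]] = np.nan
        y[[3, 4, 5]] = np.nan
        xi, yi, imputed, n_imp, n_unimp = impute_gps(t, x, y, max_gap=10)
        assert n_imp == 3 and n_unimp == 0
        assert np.allclose(xi, t * 10.0)
        assert np.allclose(yi, t * 5.0)
        assert imputed[[3, 4, 5]].all()

    def test_long_gap_left_unimputable(self):
        t = np.arange(80)
        x = np.full(80, 1.0)
        y = np.full(80, 2.0)
        x[10:70] = np.nan
        y[10:70] = np.nan
        _, _, _, n_imp, n_unimp = impute_gps(t, x, y, max_gap=10)
        assert n_imp == 0 and n_unimp == 60

    def test_gap_accounting_matches_generator(self, noisy_world, noisy_area):
        w = noisy_world
        total_imp = total_unimp = 0
        for pid, part in w.stream.groupby("participant_id"):
            part = part.sort_values("timestamp_utc")
            x, y = noisy_area.projection.to_xy(part["lon"].to_numpy(),
                                               part["lat"].to_numpy())
            t = np.arange(len(part))
            _, _, _, n_imp, n_unimp = impute_gps(t, x, y, max_gap=10)
            total_imp += n_imp
            total_unimp += n_unimp
        assert total_imp + total_unimp == int(w.truth["gps_gap"].sum())


# ---------------------------------------------------------------------------
# stay/trip segmentation and the exhaustive oracle


class TestStayDetection:
    def test_single_tight_cluster_is_one_stay(self):
        rng = np.random.default_rng(0)
        t = np.arange(30)
        x = rng.uniform(-2.5, 2.5, 30)
        y = rng.uniform(-2.5, 2.5, 30)
        segs = detect_stays_trips("p", t, x, y, eps_m=30, min_stay_min=5)
        assert len(segs) == 1
        assert segs[0].kind == "stay" and len(segs[0].minutes) == 30

    def test_stay_trip_stay_structure(self):
        # 120 min at home, straight 15-min drive, 360 min at the office
        t = np.arange(495)
        x = np.concatenate([np.zeros(120), np.linspace(0, 10000, 17)[1:-1],
                            np.full(360, 10000.0)])
        y = np.zeros(495)
        segs = detect_stays_trips("p", t, x, y, eps_m=30, min_stay_min=5)
        assert [s.kind for s in segs] == ["stay", "trip", "stay"]
        assert len(segs[0].minutes) == 120
        assert len(segs[2].minutes) == 360

    def test_time_gap_breaks_contiguity(self):
        t = np.concatenate([np.arange(30), np.arange(60, 90)])
        x = np.zeros(60)
        y = np.zeros(60)
        segs = detect_stays_trips("p", t, x, y, eps_m=30, min_stay_min=5,
                                  max_time_gap_min=10)
        assert len(segs) == 2
        assert all(s.kind == "stay" for s in segs)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 200))
        x, y = random_track(rng, n)
        t = np.arange(n)
        segs = detect_stays_trips("p", t, x, y, eps_m=30, min_stay_min=5,
                                  max_time_gap_min=10)
        got = [(int(s.minutes[0]), int(s.minutes[-1]))
               for s in segs if s.kind == "stay"]
        assert got == oracle_stay_windows(t, x, y, 30, 5)


# ---------------------------------------------------------------------------
# context assignment


class TestStayContext:
    def test_residential_stay_near_building_is_indoor(self, noiseless_world,
                                                      noiseless_area):
        ls = noiseless_world.landscape
        idx = int(ls.parcels_of_class("residential")[0])
        cx, cy = ls.parcel_centroid_xy(idx)
        # 5 m from the building centre: inside the 10-m buffer
        seg = Segment("p", "stay", np.arange(30), np.full(30, cx + 5.0),
                      np.full(30, cy))
        from pmexposure.context import assign_stay_context

        labs, n_out = assign_stay_context([seg], noiseless_area, buffer_m=10)
        assert n_out == 0
        assert labs[0]["microenv"] == "residential"
        assert labs[0]["indoor"] is True

    def test_beyond_buffer_is_outdoor(self, noiseless_world, noiseless_area):
        ls = noiseless_world.landscape
        idx = int(ls.parcels_of_class("residential")[0])
        cx, cy = ls.parcel_centroid_xy(idx)
        # building is a 16 m square at the centre: 8 m half-width + 15 m > buffer
        seg = Segment("p", "stay", np.arange(30), np.full(30, cx + 8.0 + 15.0),
                      np.full(30, cy))
        from pmexposure.context import assign_stay_context

        labs, _ = assign_stay_context([seg], noiseless_area, buffer_m=10)
        assert labs[0]["indoor"] is False

    def test_buffer_monotonicity_never_flips_indoor_to_outdoor(
        self, noiseless_world, noiseless_area
    ):
        from pmexposure.context import assign_stay_context

        ls = noiseless_world.landscape
        rng = np.random.default_rng(3)
        minx, miny, maxx, maxy = ls.region_xy.bounds
        segs = [
            Segment("p", "stay", np.arange(10),
                    np.full(10, rng.uniform(minx, maxx)),
                    np.full(10, rng.uniform(miny, maxy)))
            for _ in range(40)
        ]
        small, _ = assign_stay_context(segs, noiseless_area, buffer_m=10)
        large, _ = assign_stay_context(segs, noiseless_area, buffer_m=40)
        for a, b in zip(small, large):
            if a["indoor"]:
                assert b["indoor"]

    def test_out_of_region_stay_excluded_and_counted(self, noiseless_area):
        from pmexposure.context import assign_stay_context

        seg = Segment("p", "stay", np.arange(10), np.full(10, 1e6),
                      np.full(10, 1e6))
        labs, n_out = assign_stay_context([seg], noiseless_area)
        assert labs == [] and n_out == 1


class TestTripMode:
    def _trip(self, speed_ms, minutes):
        t = np.arange(minutes)
        return Segment("p", "trip", t, t * speed_ms * 60.0, np.zeros(minutes))

    def test_fast_trip_is_vehicle_and_indoor(self, noiseless_area):
        labs, _ = classify_trip_mode([self._trip(12.0, 8)], noiseless_area)
        assert labs[0]["mode"] == "vehicle"
        assert labs[0]["indoor"] is True
        assert set(labs[0]["microenv"]) == {"vehicle"}

    def test_stroll_is_walking_and_outdoor_with_landuse(self, noiseless_world,
                                                        noiseless_area):
        ls = noiseless_world.landscape
        idx = int(ls.parcels_of_class("park_open_space")[0])
        cx, cy = ls.parcel_centroid_xy(idx)
        t = np.arange(5)
        seg = Segment("p", "trip", t, cx + t * 1.4 * 60.0 - 168.0, np.full(5, cy))
        labs, _ = classify_trip_mode([seg], noiseless_area)
        assert labs[0]["mode"] == "walk"
        assert labs[0]["indoor"] is False
        assert "park_open_space" in set(labs[0]["microenv"])

    def test_single_fix_trip_dropped_with_warning(self, noiseless_area):
        seg = Segment("p", "trip", np.array([0]), np.array([0.0]), np.array([0.0]))
        with pytest.warns(UserWarning):
            labs, n_drop = classify_trip_mode([seg], noiseless_area)
        assert labs == [] and n_drop == 1


# ---------------------------------------------------------------------------
# end-to-end recovery and the valid-day filter


class TestRecovery:
    def test_noiseless_recovery_is_exact(self, noiseless_world, noiseless_area):
        labels, diags = identify_context(noiseless_world.stream, noiseless_area)
        assert context_accuracy(labels, noiseless_world.truth) == 1.0
        assert diags["imputed"] == 0 and diags["unimputable"] == 0

    def test_trip_mode_recovery_noiseless(self, noiseless_world, noiseless_area):
        labels, _ = identify_context(noiseless_world.stream, noiseless_area)
        truth = noiseless_world.truth
        m = labels.merge(truth[["participant_id", "timestamp_utc", "mode"]],
                         on=["participant_id", "timestamp_utc"])
        trips = m[m["mode"].isin(["walk", "vehicle"])]
        got_vehicle = trips["microenv"] == "vehicle"
        assert (got_vehicle == (trips["mode"] == "vehicle")).mean() == 1.0

    def test_partition_every_labelled_minute_once(self, noisy_world, noisy_area):
        labels, _ = identify_context(noisy_world.stream, noisy_area)
        dup = labels.duplicated(["participant_id", "timestamp_utc"])
        assert not dup.any()


class TestValidDays:
    def _labels(self, minutes_per_day):
        rows = []
        for d, m in enumerate(minutes_per_day):
            ts = pd.date_range(f"2019-06-{d+2:02d} 08:00", periods=m, freq="min",
                               tz="UTC")
            for t in ts:
                rows.append(("A", t, "residential", True, "s", "stay"))
        return pd.DataFrame(rows, columns=["participant_id", "timestamp_utc",
                                           "microenv", "indoor", "segment_id",
                                           "segment_kind"])

    def test_359_minutes_dropped_360_retained(self):
        labels = self._labels([359, 360])
        kept, dropped = filter_valid_days(labels, min_hours=6)
        days_kept = pd.DatetimeIndex(kept["timestamp_utc"]).day.unique()
        assert len(days_kept) == 1
        assert len(dropped) == 1 and dropped["minutes"].iloc[0] == 359

    def test_sparse_days_removed_from_two_week_window(self):
        minutes = [500] * 14
        minutes[3] = 100
        minutes[9] = 200
        labels = self._labels(minutes)
        kept, dropped = filter_valid_days(labels, min_hours=6)
        local_days = pd.DatetimeIndex(kept["timestamp_utc"]).tz_convert(
            "America/Los_Angeles"
        ).date
        assert len(set(local_days)) == 12
        assert len(dropped) == 2
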