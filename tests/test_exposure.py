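import numpy as np
import pandas as pd
import pytest

from pmexposure.exposure import (
    compare_personal_home,
    dose_apportion,
    idw_home,
    summarize,
    time_budget,
)
from pmexposure.geo import LocalProjection

PROJ = LocalProjection(-122.33, 47.61)


def _labeled(n=100, conc=5.0, microenv="residential", indoor=True, pid="A"):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp_utc": pd.date_range("2019-01-01", periods=n, freq="min",
                                           tz="UTC"),
            "microenv": microenv,
            "indoor": indoor,
            "pm25_calibrated": conc,
        }
    )


class TestSummarize:
    def test_constant_stream_collapses_all_statistics(self):
        out = summarize(_labeled(50, conc=5.0))
        row = out.iloc[0]
        assert row["mean"] == 5.0 and row["sd"] == 0.0
        for c in ("p2.5", "p25", "p50", "p75", "p97.5", "min", "max"):
            assert row[c] == 5.0

    def test_median_uses_linear_interpolation_rule(self):
        df = _labeled(100)
        df["pm25_calibrated"] = np.arange(1.0, 101.0)
        out = summarize(df)
        assert out["p50"].iloc[0] == 50.5
        # independent oracle: sort and interpolate by the declared rule
        v = np.sort(df["pm25_calibrated"].to_numpy())
        k = 0.25 * (len(v) - 1)
        expected_p25 = v[int(k)] + (k - int(k)) * (v[int(k) + 1] - v[int(k)])
        assert out["p25"].iloc[0] == pytest.approx(expected_p25)

    def test_grouping_emits_one_row_per_observed_group(self):
        frames = [_labeled(10, microenv=m) for m in
                  ("residential", "office", "vehicle")]
        out = summarize(pd.concat(frames), group_by="microenv")
        assert len(out) == 3
        assert set(out["microenv"]) == {"residential", "office", "vehicle"}

    def test_unknown_grouping_key_raises(self):
        with pytest.raises(KeyError):
            summarize(_labeled(), group_by="nope")

    def test_percentile_ordering_invariant(self):
        rng = np.random.default_rng(7)
        df = _labeled(500)
        df["pm25_calibrated"] = rng.lognormal(1.5, 1.0, 500)
        r = summarize(df).iloc[0]
        seq = [r["min"], r["p2.5"], r["p25"], r["p50"], r["p75"], r["p97.5"], r["max"]]
        assert all(a <= b for a, b in zip(seq, seq[1:]))


class TestDose:
    def test_uniform_concentration_makes_dose_equal_time_share(self):
        df = pd.concat([
            _labeled(300, conc=7.0, microenv="residential"),
            _labeled(100, conc=7.0, microenv="office"),
        ])
        d = dose_apportion(df)
        by = d.by_microenv.set_index("microenv")["proportion"]
        assert by["residential"] == pytest.approx(0.75)
        assert by["office"] == pytest.approx(0.25)

    def test_single_microenvironment_takes_full_share(self):
        d = dose_apportion(_labeled(200, microenv="residential", indoor=True))
        assert d.by_microenv["proportion"].iloc[0] == pytest.approx(1.0)
        io = d.by_indoor.set_index("indoor")["proportion"]
        assert io[True] == pytest.approx(1.0)

    def test_breathing_rate_invariance_of_proportions(self):
        rng = np.random.default_rng(2)
        df = pd.concat([
            _labeled(120, conc=3.0, microenv="residential"),
            _labeled(60, conc=11.0, microenv="vehicle"),
        ])
        a = dose_apportion(df, breathing_rate=0.012)
        b = dose_apportion(df, breathing_rate=0.024)
        assert np.allclose(a.by_microenv["proportion"], b.by_microenv["proportion"])
        assert b.total_dose_ug == pytest.approx(2 * a.total_dose_ug)

    def test_proportions_always_sum_to_one(self):
        rng = np.random.default_rng(3)
        df = pd.concat([
            _labeled(50, conc=float(c), microenv=m)
            for c, m in zip(rng.uniform(1, 30, 5),
                            ["residential", "office", "vehicle", "commercial",
                             "park_open_space"])
        ])
        d = dose_apportion(df)
        assert d.by_microenv["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert d.by_indoor["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_dose_is_an_error(self):
        with pytest.raises(ValueError):
            dose_apportion(_labeled(10, conc=0.0))


class TestTimeBudget:
    def test_fractions_sum_to_one_and_match_generator_target(self, noisy_world):
        me, io = time_budget(noisy_world.truth.rename(columns={"mode": "segment_kind"}))
        assert me["fraction"].sum() == pytest.approx(1.0)
        indoor_frac = io.set_index("indoor")["fraction"][True]
        assert abs(indoor_frac - noisy_world.config.indoor_target) <= 0.05

    def test_single_label_stream(self):
        me, io = time_budget(_labeled(60))
        assert len(me) == 1 and me["fraction"].iloc[0] == 1.0


def _stations(values, offsets_m, hours=3):
    ts = pd.date_range("2019-01-01", periods=hours, freq="h", tz="UTC")
    frames = []
    for k, (v, off) in enumerate(zip(values, offsets_m)):
        lon, lat = PROJ.to_lonlat(off[0], off[1])
        frames.append(pd.DataFrame({
            "station_id": f"S{k:03d}", "lat": float(lat), "lon": float(lon),
            "timestamp_utc": ts, "pm25": v,
        }))
    return pd.concat(frames, ignore_index=True)


class TestIDW:
    def test_home_at_station_returns_station_series(self):
        st = _stations([4.0, 9.0], [(0.0, 0.0), (5000.0, 0.0)])
        home = PROJ.to_lonlat(0.0, 0.0)
        series, _, n_missing = idw_home(st, (float(home[0]), float(home[1])), PROJ)
        assert np.allclose(series["pm25_idw"], 4.0)
        assert n_missing == 0

    def test_equidistant_stations_average(self):
        st = _stations([4.0, 8.0], [(-1000.0, 0.0), (1000.0, 0.0)])
        home = PROJ.to_lonlat(0.0, 0.0)
        series, weights, _ = idw_home(st, (float(home[0]), float(home[1])), PROJ)
        assert np.allclose(series["pm25_idw"], 6.0)
        assert weights["weight"].sum() == pytest.approx(1.0)

    def test_three_station_hand_computed_oracle(self):
        d = np.array([1000.0, 2000.0, 4000.0])
        v = np.array([10.0, 6.0, 2.0])
        st = _stations(v, [(d[0], 0.0), (0.0, d[1]), (-d[2], 0.0)])
        home = PROJ.to_lonlat(0.0, 0.0)
        series, _, _ = idw_home(st, (float(home[0]), float(home[1])), PROJ, power=2)
        w = d ** -2.0
        expected = float((w * v).sum() / w.sum())
        assert np.allclose(series["pm25_idw"], expected, rtol=1e-6)

    def test_high_power_approaches_nearest_neighbour(self):
        st = _stations([10.0, 2.0], [(1000.0, 0.0), (3000.0, 0.0)])
        home = PROJ.to_lonlat(0.0, 0.0)
        series, _, _ = idw_home(st, (float(home[0]), float(home[1])), PROJ, power=40)
        assert np.allclose(series["pm25_idw"], 10.0, atol=1e-6)

    def test_out_of_radius_hours_counted_missing(self):
        st = _stations([5.0], [(60_000.0, 0.0)])
        home = PROJ.to_lonlat(0.0, 0.0)
        series, _, n_missing = idw_home(st, (float(home[0]), float(home[1])), PROJ,
                                        max_radius_km=50.0)
        assert n_missing == len(series)


class TestPersonalHomeComparison:
    def _personal(self, values, pid="A"):
        return pd.DataFrame({
            "participant_id": pid,
            "timestamp_utc": pd.date_range("2019-01-01", periods=len(values),
                                           freq="min", tz="UTC"),
            "pm25_calibrated": values,
        })

    def _home(self, values, pid="A"):
        return pd.DataFrame({
            "participant_id": pid,
            "timestamp_utc": pd.date_range("2019-01-01", periods=len(values),
                                           freq="h", tz="UTC"),
            "pm25_idw": values,
        })

    def test_identical_series_give_unit_correlation_and_ratio(self):
        home_vals = [3.0, 7.0, 5.0]
        personal = self._personal(np.repeat(home_vals, 60))
        out = compare_personal_home(personal, self._home(home_vals))
        assert out["pearson_r_minute"] == pytest.approx(1.0)
        assert out["pearson_r_hour"] == pytest.approx(1.0)
        assert out["po_median"] == pytest.approx(1.0)

    def test_constant_home_series_flagged_undefined(self):
        personal = self._personal(np.arange(120.0) + 1)
        out = compare_personal_home(personal, self._home([5.0, 5.0]))
        assert out["constant_home"]
        assert np.isnan(out["pearson_r_minute"])

    def test_indoor_spikes_depress_minute_correlation(self):
        rng = np.random.default_rng(9)
        base = np.repeat(rng.uniform(3, 9, 24), 60)
        home = self._home(base[::60])
        rs = []
        for spike_sd in (0.0, 10.0, 40.0):
            noise = rng.normal(0, spike_sd, base.size).clip(min=0)
            out = compare_personal_home(self._personal(base + noise), home)
            rs.append(out["pearson_r_minute"])
        assert rs[0] == pytest.approx(1.0)
        assert rs[0] > rs[1] > rs[2]

    def test_too_little_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            compare_personal_home(self._personal([5.0]), self._home([5.0]))

    def test_hourly_aggregation_smooths_spikes_across_seeds(self):
        wins = 0
        for seed in range(7):
            rng = np.random.default_rng(seed)
            base = np.repeat(rng.uniform(3, 9, 48), 60)
            spikes = rng.exponential(8.0, base.size) * (rng.random(base.size) < 0.05)
            out = compare_personal_home(self._personal(base + spikes),
                                        self._home(base[::60]))
            wins += int(out["pearson_r_hour"] >= out["pearson_r_minute"])
        assert wins >= 4  # majority of seeds
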