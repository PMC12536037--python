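"""Minute-level sensor streams, hourly station series, and ground truth.

Pollution model
---------------
Regional ambient PM2.5 (hourly): ``A0 + As*cos(2*pi*doy/365) +
Ad*cos(2*pi*(hour_local-19)/24) + AR(1) noise``, shared across the region,
producing winter and evening maxima. Stations report this series without
error (decorrelated stations get an independent series of the same marginal
character, for cut-off-scan experiments). True personal exposure is the
ambient value outdoors, and ``infiltration*ambient`` indoors and in
vehicles, plus episodic indoor sources at home: a dinnertime cooking peak
(Gaussian in local time, lognormal amplitude) and a constant heating boost
in winter.

Sensor model
------------
The optical sensor reports ``raw = (truth - intercept)/slope`` times
mean-one multiplicative lognormal noise, so a linear fit of reference on
raw recovers (slope, intercept). Particle counts are derived from raw mass
with fixed, decreasing per-bin factors (so count bins are monotone).
GPS fixes are the true position plus isotropic noise; whole minutes lose
their fix with the configured gap probability, never their pollution data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from pmexposure.config import WorldConfig
from pmexposure.io import MASS_COLS, PNC_COLS, STREAM_COLS
from pmexposure.synthetic.landscape import Landscape, generate_landscape
from pmexposure.synthetic.schedule import Schedule, generate_schedule

_PNC_PER_UG = np.array([900.0, 260.0, 45.0, 8.0, 1.5, 0.3])
_AMBIENT_FLOOR = 0.3  # ug/m3, keeps the field physical


@dataclass
class World:
    config: WorldConfig
    landscape: Landscape
    schedules: list[Schedule]
    stream: pd.DataFrame  # minute records, STREAM_COLS
    stations: pd.DataFrame  # station_id, lat, lon, timestamp_utc, pm25
    truth: pd.DataFrame  # per-minute ground truth
    demographics: pd.DataFrame

    def homes(self) -> pd.DataFrame:
        """Ground-truth home coordinate (lon/lat) per participant."""
        rows = []
        for s in self.schedules:
            home = next(e for e in s.entries if e.kind == "stay")
            lon, lat = self.landscape.projection.to_lonlat(home.x0, home.y0)
            rows.append({"participant_id": s.participant_id,
                         "lon": float(lon), "lat": float(lat)})
        return pd.DataFrame(rows)


def _local_fields(ts_utc: pd.DatetimeIndex, tz: str):
    loc = ts_utc.tz_convert(tz)
    return loc.dayofyear.to_numpy(), loc.hour.to_numpy(), (
        loc.hour * 60 + loc.minute
    ).to_numpy(), loc.month.to_numpy()


def ambient_deterministic(config: WorldConfig, hours_utc: pd.DatetimeIndex) -> np.ndarray:
    """Closed-form seasonal+diurnal component of the regional ambient field."""
    doy, hour, _, _ = _local_fields(hours_utc, config.timezone)
    return (
        config.ambient_base
        + config.ambient_seasonal_amp * np.cos(2 * np.pi * doy / 365.0)
        + config.ambient_diurnal_amp * np.cos(2 * np.pi * (hour - 19) / 24.0)
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, n)
    out = np.empty(n)
    out[0] = innov[0] / np.sqrt(max(1e-12, 1 - phi**2))
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def _hour_index(ts: pd.DatetimeIndex, hours: pd.DatetimeIndex) -> np.ndarray:
    return ((ts.asi8 - hours.asi8[0]) // (3600 * 10**9)).astype(np.int64)


def expand_schedule(schedule: Schedule, landscape: Landscape) -> pd.DataFrame:
    """Per-minute ground-truth position and context for one participant."""
    n = schedule.n_minutes
    x = np.empty(n)
    y = np.empty(n)
    microenv = np.empty(n, dtype=object)
    indoor = np.zeros(n, dtype=bool)
    mode = np.full(n, "stay", dtype=object)
    seg = np.empty(n, dtype=object)
    walk_rows: list[np.ndarray] = []
    for k, e in enumerate(schedule.entries):
        sl = slice(e.start_min, e.end_min)
        seg[sl] = f"{schedule.participant_id}:{k:04d}"
        indoor[sl] = e.indoor
        if e.kind == "stay":
            x[sl] = e.x0
            y[sl] = e.y0
            microenv[sl] = e.landuse
        else:
            # fixes sit strictly between the endpoints so a trip's first and
            # last fixes are off the adjacent stay locations
            frac = (np.arange(e.duration) + 1.0) / (e.duration + 1.0)
            x[sl] = e.x0 + frac * (e.x1 - e.x0)
            y[sl] = e.y0 + frac * (e.y1 - e.y0)
            mode[sl] = e.mode
            if e.mode == "vehicle":
                microenv[sl] = "vehicle"
            else:
                walk_rows.append(np.arange(e.start_min, e.end_min))
    if walk_rows:
        rows = np.concatenate(walk_rows)
        pts = shapely.points(x[rows], y[rows])
        microenv[rows] = landscape.nearest_class(pts)
    ts = schedule.start_utc + pd.to_timedelta(np.arange(n), unit="min")
    return pd.DataFrame(
        {
            "participant_id": schedule.participant_id,
            "timestamp_utc": ts,
            "x": x,
            "y": y,
            "microenv": microenv,
            "indoor": indoor,
            "mode": mode,
            "segment_id": seg,
        }
    )


def _true_exposure(
    config: WorldConfig, truth: pd.DataFrame, ambient: np.ndarray, hidx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    amb = ambient[hidx]
    conc = np.where(truth["indoor"].to_numpy(), config.indoor_infiltration * amb, amb)
    at_home = (truth["microenv"].to_numpy() == "residential") & truth["indoor"].to_numpy()
    _, _, lmin, month = _local_fields(pd.DatetimeIndex(truth["timestamp_utc"]), config.timezone)
    winter = np.isin(month, (12, 1, 2))
    conc = conc + np.where(at_home & winter, config.winter_heating_boost, 0.0)
    # one dinnertime cooking event per home-day, lognormal amplitude
    n_days = len(conc) // 1440
    peak = config.cooking_peak_hour * 60
    for d in range(n_days):
        if rng.random() >= config.cooking_prob:
            continue
        amp = config.cooking_peak_ug * rng.lognormal(0.0, 0.4)
        sl = slice(d * 1440, (d + 1) * 1440)
        bump = amp * np.exp(-0.5 * ((lmin[sl] - peak) / 45.0) ** 2)
        conc[sl] = conc[sl] + np.where(at_home[sl], bump, 0.0)
    return conc


def generate_streams(
    config: WorldConfig, schedules: list[Schedule], landscape: Landscape
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (personal minute stream, hourly station series, ground truth)."""
    start = min(s.start_utc for s in schedules).floor("h")
    end = max(s.start_utc + pd.Timedelta(minutes=s.n_minutes) for s in schedules).ceil("h")
    hours = pd.date_range(start, end, freq="h", inclusive="left")

    rng_amb = np.random.default_rng([config.seed, 3])
    regional = ambient_deterministic(config, hours) + _ar1(
        rng_amb, len(hours), config.ambient_ar_phi, config.ambient_ar_sd
    )
    regional = np.maximum(regional, _AMBIENT_FLOOR)

    station_frames = []
    for i, st in landscape.stations.iterrows():
        if st["decorrelated"]:
            srng = np.random.default_rng([config.seed, 4, int(i)])
            phase = srng.uniform(0, 24)
            doy, hour, _, _ = _local_fields(hours, config.timezone)
            series = (
                config.ambient_base
                + config.ambient_diurnal_amp * np.cos(2 * np.pi * (hour - phase) / 24.0)
                + _ar1(srng, len(hours), config.ambient_ar_phi,
                       max(config.ambient_ar_sd, 1.0) * 2.5)
            )
            series = np.maximum(series, _AMBIENT_FLOOR)
        else:
            series = regional
        station_frames.append(
            pd.DataFrame(
                {
                    "station_id": st["station_id"],
                    "lat": st["lat"],
                    "lon": st["lon"],
                    "timestamp_utc": hours,
                    "pm25": series,
                }
            )
        )
    stations = pd.concat(station_frames, ignore_index=True)

    stream_frames = []
    truth_frames = []
    for idx, sched in enumerate(schedules):
        truth = expand_schedule(sched, landscape)
        ts = pd.DatetimeIndex(truth["timestamp_utc"])
        hidx = _hour_index(ts, hours)
        rng_p = np.random.default_rng([config.seed, 5, idx])
        conc = _true_exposure(config, truth, regional, hidx, rng_p)
        truth["true_pm25"] = conc

        raw = (conc - config.sensor_intercept) / config.sensor_slope
        if config.sensor_noise_sd > 0:
            sig = config.sensor_noise_sd
            raw = raw * np.exp(rng_p.normal(0.0, sig, len(raw)) - sig**2 / 2)
        raw = np.maximum(raw, 0.0)

        gaps = rng_p.random(len(raw)) < config.gps_gap_rate
        gx = truth["x"].to_numpy() + rng_p.normal(0.0, config.gps_noise_sd, len(raw))
        gy = truth["y"].to_numpy() + rng_p.normal(0.0, config.gps_noise_sd, len(raw))
        lon, lat = landscape.projection.to_lonlat(gx, gy)
        lon[gaps] = np.nan
        lat[gaps] = np.nan
        truth["gps_gap"] = gaps

        doy, hour, _, _ = _local_fields(ts, config.timezone)
        temp = (
            11.0
            - 9.0 * np.cos(2 * np.pi * (doy - 15) / 365.0)
            + 4.0 * np.cos(2 * np.pi * (hour - 15) / 24.0)
            + rng_p.normal(0.0, 0.5, len(raw))
        )
        rh = np.clip(
            72.0
            + 12.0 * np.cos(2 * np.pi * (doy - 15) / 365.0)
            - 8.0 * np.cos(2 * np.pi * (hour - 15) / 24.0)
            + rng_p.normal(0.0, 2.0, len(raw)),
            20.0,
            100.0,
        )

        rec = pd.DataFrame({"participant_id": sched.participant_id, "timestamp_utc": ts})
        zero_out = idx < config.zero_sensor_participants
        for j, col in enumerate(PNC_COLS):
            rec[col] = 0 if zero_out else np.floor(raw * _PNC_PER_UG[j]).astype(np.int64)
        rec[MASS_COLS[0]] = 0.0 if zero_out else 0.6 * raw
        rec[MASS_COLS[1]] = 0.0 if zero_out else raw
        rec[MASS_COLS[2]] = 0.0 if zero_out else 1.4 * raw
        rec["temp_c"] = temp
        rec["rh_pct"] = rh
        rec["lat"] = lat
        rec["lon"] = lon
        stream_frames.append(rec[STREAM_COLS])
        truth_frames.append(truth)

    stream = pd.concat(stream_frames, ignore_index=True)
    truth_df = pd.concat(truth_frames, ignore_index=True)
    return stream, stations, truth_df


def generate_demographics(config: WorldConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 6])
    n = config.n_participants
    pick = lambda levels, p: rng.choice(np.array(levels, dtype=object), size=n, p=p)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age_group": pick(["0-29", "30-39", "40-49", "50-59", "60+"],
                              [0.13, 0.51, 0.09, 0.21, 0.06]),
            "sex": pick(["female", "male"], [0.79, 0.21]),
            "marital": pick(["unmarried", "married"], [0.41, 0.59]),
            "race": pick(["non-white", "white"], [0.06, 0.94]),
            "edu": pick(["lt_ba", "ba", "gt_ba"], [0.21, 0.44, 0.35]),
            "income": pick(["low", "high"], [0.36, 0.64]),
        }
    )


def generate_world(config: WorldConfig) -> World:
    landscape = generate_landscape(config)
    schedules = [
        generate_schedule(config, landscape, i) for i in range(config.n_participants)
    ]
    stream, stations, truth = generate_streams(config, schedules, landscape)
    demographics = generate_demographics(config)
    return World(config, landscape, schedules, stream, stations, truth, demographics)


def write_world(world: World, outdir) -> list[str]:
    from pathlib import Path

    from pmexposure import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = world.landscape.write(outdir)
    pio.write_stream(world.stream, outdir / "personal.csv")
    pio.write_stations(world.stations, outdir / "stations.csv")
    world.demographics.to_csv(outdir / "demographics.csv", index=False)
    world.homes().to_csv(outdir / "homes.csv", index=False, float_format="%.6f")
    truth = world.truth.copy()
    truth["timestamp_utc"] = pd.DatetimeIndex(truth["timestamp_utc"]).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    return files + [
        "personal.csv",
        "stations.csv",
        "demographics.csv",
        "homes.csv",
        "ground_truth.csv",
    ]
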