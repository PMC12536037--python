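"""Ground-truth daily activity schedules.

Each participant gets a home (residential building), a workplace (office
building; a commercial venue at weekends), and a nearby park. A day is a
fixed skeleton — home overnight, a morning park excursion on foot, a vehicle
commute to an indoor work block, home in the evening — whose stay durations
are solved so the realized indoor-time and residential-time fractions hit
the configured targets, with seeded minute-level jitter. Trips run at
constant speed along straight lines between consecutive visit locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmexposure.config import ConfigError, WorldConfig
from pmexposure.synthetic.landscape import Landscape

MIN_PER_DAY = 1440


@dataclass
class Entry:
    kind: str  # "stay" | "trip"
    start_min: int
    end_min: int  # exclusive
    x0: float
    y0: float
    x1: float
    y1: float
    landuse: str | None  # stay class; None for trips (walk label is per-minute)
    indoor: bool
    mode: str | None  # None | "walk" | "vehicle"

    @property
    def duration(self) -> int:
        return self.end_min - self.start_min


@dataclass
class Schedule:
    participant_id: str
    start_utc: pd.Timestamp
    n_minutes: int
    entries: list[Entry]

    def indoor_fraction(self) -> float:
        indoor = sum(e.duration for e in self.entries if e.indoor)
        return indoor / self.n_minutes

    def stays(self) -> list[Entry]:
        return [e for e in self.entries if e.kind == "stay"]

    def trips(self) -> list[Entry]:
        return [e for e in self.entries if e.kind == "trip"]


def _trip_minutes(dist_m: float, speed_ms: float) -> int:
    # at least 2 minutes so every trip has the >=2 fixes mode detection needs
    return max(2, int(round(dist_m / speed_ms / 60.0)))


def _pick_nearest(landscape: Landscape, cls: str, x: float, y: float,
                  min_dist: float = 0.0, max_dist: float = math.inf) -> int:
    idxs = landscape.parcels_of_class(cls)
    if len(idxs) == 0:
        raise ConfigError(f"landscape has no {cls} parcel")
    cents = np.array([landscape.parcel_centroid_xy(i) for i in idxs])
    d = np.hypot(cents[:, 0] - x, cents[:, 1] - y)
    ok = (d >= min_dist) & (d <= max_dist)
    if not ok.any():
        ok = d >= min_dist  # relax the upper bound first
    if not ok.any():
        return int(idxs[np.argmax(d)])  # everything too close: take the farthest
    cand = np.flatnonzero(ok)
    return int(idxs[cand[np.argmin(d[cand])]])


def generate_schedule(config: WorldConfig, landscape: Landscape, idx: int) -> Schedule:
    rng = np.random.default_rng([config.seed, 2, idx])
    pid = f"P{idx:04d}"

    offset = int(rng.integers(0, config.stagger_days + 1))
    start_local = pd.Timestamp(config.study_start, tz=config.timezone) + pd.Timedelta(days=offset)
    start_utc = start_local.tz_convert("UTC")
    n_minutes = config.n_days * MIN_PER_DAY
    if n_minutes < 1:
        raise ConfigError("monitoring window shorter than one minute")

    # anchor the home, then place the rest of this participant's world
    res = landscape.parcels_of_class("residential")
    if config.home_anchor_points is not None:
        anchors = np.asarray(config.home_anchor_points, dtype=float)
        a = anchors[idx % len(anchors)]
        ax, ay = landscape.projection.to_xy(a[0], a[1])
        home_parcel = _pick_nearest(landscape, "residential", float(ax), float(ay))
    else:
        home_parcel = int(rng.choice(res))
    hx, hy = landscape.parcel_centroid_xy(home_parcel)

    if config.indoor_target >= 0.999:
        entries = [Entry("stay", 0, n_minutes, hx, hy, hx, hy, "residential", True, None)]
        return Schedule(pid, start_utc, n_minutes, entries)

    park_parcel = _pick_nearest(landscape, "park_open_space", hx, hy, min_dist=180.0)
    px, py = landscape.parcel_centroid_xy(park_parcel)
    office_parcel = _pick_nearest(landscape, "office", hx, hy, min_dist=1500.0, max_dist=12000.0)
    ox, oy = landscape.parcel_centroid_xy(office_parcel)
    comm_parcel = _pick_nearest(landscape, "commercial", hx, hy, min_dist=1500.0)
    cx, cy = landscape.parcel_centroid_xy(comm_parcel)

    w_out = _trip_minutes(math.hypot(px - hx, py - hy), config.walk_speed)
    walks = 2 * w_out
    d_work = _trip_minutes(math.hypot(ox - hx, oy - hy), config.vehicle_speed)
    d_comm = _trip_minutes(math.hypot(cx - hx, cy - hy), config.vehicle_speed)

    outdoor_budget = int(round((1.0 - config.indoor_target) * MIN_PER_DAY))
    park_base = max(0, outdoor_budget - walks)
    home_budget = int(round(config.residential_target * MIN_PER_DAY))
    work_base = MIN_PER_DAY - home_budget - park_base - walks - 2 * d_work
    work_base = max(0, work_base)

    entries: list[Entry] = []
    for day in range(config.n_days):
        base = day * MIN_PER_DAY
        weekday = (start_local + pd.Timedelta(days=day)).weekday()
        weekend = weekday >= 5
        wx, wy = (cx, cy) if weekend else (ox, oy)
        drive = d_comm if weekend else d_work
        work_cls = "commercial" if weekend else "office"

        m1 = 420 + int(rng.integers(-20, 21))
        park = max(0, park_base + int(rng.integers(-10, 11)))
        work = work_base
        # keep the day inside 1440 minutes with an evening-home remainder
        used = m1 + (walks + park if park > 0 else 0) + 15 + 2 * drive + work
        if used > MIN_PER_DAY - 30:
            work = max(0, work - (used - (MIN_PER_DAY - 30)))

        t = base
        entries.append(Entry("stay", t, t + m1, hx, hy, hx, hy, "residential", True, None))
        t += m1
        if park > 0:
            entries.append(Entry("trip", t, t + w_out, hx, hy, px, py, None, False, "walk"))
            t += w_out
            entries.append(Entry("stay", t, t + park, px, py, px, py, "park_open_space", False, None))
            t += park
            entries.append(Entry("trip", t, t + w_out, px, py, hx, hy, None, False, "walk"))
            t += w_out
        entries.append(Entry("stay", t, t + 15, hx, hy, hx, hy, "residential", True, None))
        t += 15
        if work > 0:
            entries.append(Entry("trip", t, t + drive, hx, hy, wx, wy, None, True, "vehicle"))
            t += drive
            entries.append(Entry("stay", t, t + work, wx, wy, wx, wy, work_cls, True, None))
            t += work
            entries.append(Entry("trip", t, t + drive, wx, wy, hx, hy, None, True, "vehicle"))
            t += drive
        entries.append(
            Entry("stay", t, base + MIN_PER_DAY, hx, hy, hx, hy, "residential", True, None)
        )

    entries = _merge_adjacent_stays(entries)
    return Schedule(pid, start_utc, n_minutes, entries)


def _merge_adjacent_stays(entries: list[Entry]) -> list[Entry]:
    out: list[Entry] = []
    for e in entries:
        if (
            out
            and e.kind == "stay"
            and out[-1].kind == "stay"
            and out[-1].end_min == e.start_min
            and (out[-1].x0, out[-1].y0) == (e.x0, e.y0)
        ):
            out[-1].end_min = e.end_min
        else:
            out.append(e)
    return out
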