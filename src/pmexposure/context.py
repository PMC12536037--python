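"""Microenvironment context identification from GPS trajectories.

Per participant: GPS fixes are median-smoothed, short gaps are linearly
imputed in the local metric projection, and the fix sequence is segmented
into stays (temporally contiguous runs that remain within ``eps_m`` of the
running cluster centroid for at least ``min_stay_min``) and trips (the
contiguous remainder). Stays take the class of the nearest land-use parcel
and are indoor when the stay centroid lies within a small buffer of any
building footprint; stays outside the study region are excluded. Trips are
split into vehicle-based (labelled ``vehicle``, treated as indoor) and
walking-based (outdoor, labelled per minute with the nearest land-use
class) using mean/sd of speed and travel distance. Finally, participant-
days with too few labelled minutes are removed entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from pmexposure.config import ContextParams
from pmexposure.geo import LocalProjection, projection_for, read_geojson, read_landuse


class GeometryError(ValueError):
    pass


@dataclass
class StudyArea:
    """Land-use parcels, buildings, and region boundary in the local frame."""

    projection: LocalProjection
    parcels: np.ndarray  # geometries, local metres
    parcel_class: np.ndarray
    buildings: np.ndarray
    region: Polygon  # lon/lat
    _parcel_tree: STRtree = field(default=None, repr=False)
    _building_tree: STRtree = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.parcels) == 0:
            raise GeometryError("empty land-use layer")
        self._parcel_tree = STRtree(list(self.parcels))
        self._building_tree = STRtree(list(self.buildings)) if len(self.buildings) else None

    @classmethod
    def from_landscape(cls, landscape) -> "StudyArea":
        return cls(
            projection=landscape.projection,
            parcels=landscape.parcels,
            parcel_class=landscape.parcel_class,
            buildings=landscape.buildings,
            region=landscape.region,
        )

    @classmethod
    def from_geojson(cls, landuse_path, buildings_path, region_path) -> "StudyArea":
        region_feats = read_geojson(region_path)
        if not region_feats:
            raise GeometryError(f"{region_path}: no region feature")
        region = region_feats[0][0]
        proj = projection_for(region)
        landuse = read_landuse(landuse_path)
        parcels = np.array([proj.project_geometry(g) for g, _ in landuse], dtype=object)
        classes = np.array([c for _, c in landuse], dtype=object)
        buildings = np.array(
            [proj.project_geometry(g) for g, _ in read_geojson(buildings_path)], dtype=object
        )
        return cls(proj, parcels, classes, buildings, region)

    def nearest_class(self, points) -> np.ndarray:
        from pmexposure.geo import nearest_with_ties

        idx = nearest_with_ties(self._parcel_tree, self.parcels, points)
        return self.parcel_class[idx]

    def near_building(self, points, buffer_m: float) -> np.ndarray:
        pts = np.asarray(points, dtype=object)
        out = np.zeros(len(pts), dtype=bool)
        if self._building_tree is None:
            return out
        hit = self._building_tree.query(pts, predicate="dwithin", distance=buffer_m)
        out[np.unique(hit[0])] = True
        return out

    def in_region(self, lon, lat) -> np.ndarray:
        return shapely.contains(self.region, shapely.points(lon, lat))


# ---------------------------------------------------------------------------
# Smoothing and imputation


def moving_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving median; the window shrinks symmetrically at the edges."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = len(values)
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = np.median(values[i - k : i + k + 1])
    return out


def smooth_gps(x: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Component-wise moving median over the present-fix sequence.

    Missing fixes (NaN) are preserved; the window slides over the sequence
    of present fixes only.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    present = ~(np.isnan(x) | np.isnan(y))
    if present.sum() > 0:
        x[present] = moving_median(x[present], window)
        y[present] = moving_median(y[present], window)
    return x, y


def impute_gps(
    t_min: np.ndarray, x: np.ndarray, y: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Fill interior gaps of <= ``max_gap`` minutes by linear interpolation.

    ``t_min`` is the minute offset of each slot; slots with NaN coordinates
    are gaps. Returns (x, y, imputed_mask, n_imputed, n_unimputable);
    longer gaps (and leading/trailing ones) stay missing.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    n = len(x)
    present = ~(np.isnan(x) | np.isnan(y))
    imputed = np.zeros(n, dtype=bool)
    n_imp = n_unimp = 0
    idx = np.flatnonzero(present)
    if len(idx) == 0:
        return x, y, imputed, 0, int(n)
    # leading / trailing gaps are unimputable
    n_unimp += int(idx[0]) + int(n - 1 - idx[-1])
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        span_min = t_min[b] - t_min[a]
        if gap <= max_gap:
            frac = (t_min[a + 1 : b] - t_min[a]) / span_min
            x[a + 1 : b] = x[a] + frac * (x[b] - x[a])
            y[a + 1 : b] = y[a] + frac * (y[b] - y[a])
            imputed[a + 1 : b] = True
            n_imp += gap
        else:
            n_unimp += gap
    return x, y, imputed, int(n_imp), int(n_unimp)


# ---------------------------------------------------------------------------
# Stay / trip segmentation


@dataclass
class Segment:
    participant_id: str
    kind: str  # "stay" | "trip"
    minutes: np.ndarray  # minute offsets (ascending, contiguous in fix order)
    x: np.ndarray
    y: np.ndarray

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())

    @property
    def duration_min(self) -> int:
        return int(self.minutes[-1] - self.minutes[0] + 1)


def _scan_chunk(t: np.ndarray, x: np.ndarray, y: np.ndarray, eps: float, min_dur: int):
    """Greedy maximal eps-bounded windows; returns list of (i, j, is_stay)."""
    n = len(t)
    stays = []
    claimed = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j + 1 < n:
            k = j + 1
            cx = x[i : k + 1].mean()
            cy = y[i : k + 1].mean()
            if np.max((x[i : k + 1] - cx) ** 2 + (y[i : k + 1] - cy) ** 2) <= eps**2:
                j = k
            else:
                break
        if t[j] - t[i] + 1 >= min_dur:
            stays.append((i, j))
            claimed[i : j + 1] = True
            i = j + 1
        else:
            i += 1
    return stays, claimed


def detect_stays_trips(
    participant_id: str,
    t_min: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    eps_m: float = 30.0,
    min_stay_min: int = 5,
    max_time_gap_min: int = 10,
) -> list[Segment]:
    """Segment a GPS-bearing fix sequence into stays and trips.

    Stays are maximal windows whose members all lie within ``eps_m`` of the
    window centroid for at least ``min_stay_min`` minutes; the contiguous
    remainder forms trips. Contiguity breaks across time gaps longer than
    ``max_time_gap_min``.
    """
    t_min = np.asarray(t_min)
    if len(t_min) == 0:
        return []
    order = np.argsort(t_min, kind="stable")
    t_min, x, y = t_min[order], np.asarray(x)[order], np.asarray(y)[order]
    breaks = np.flatnonzero(np.diff(t_min) > max_time_gap_min) + 1
    segments: list[Segment] = []
    for chunk in np.split(np.arange(len(t_min)), breaks):
        ct, cx, cy = t_min[chunk], x[chunk], y[chunk]
        stays, claimed = _scan_chunk(ct, cx, cy, eps_m, min_stay_min)
        marks = np.zeros(len(chunk), dtype=int)  # 0 unclaimed, 1.. stay ordinal
        for s, (i, j) in enumerate(stays, start=1):
            marks[i : j + 1] = s
        # emit stays and the maximal unclaimed runs (trips) in time order
        pos = 0
        while pos < len(chunk):
            m = marks[pos]
            end = pos
            while end + 1 < len(chunk) and marks[end + 1] == m:
                end += 1
            kind = "stay" if m > 0 else "trip"
            segments.append(
                Segment(participant_id, kind, ct[pos : end + 1], cx[pos : end + 1], cy[pos : end + 1])
            )
            pos = end + 1
    return segments


# ---------------------------------------------------------------------------
# Context assignment


def assign_stay_context(
    stays: Iterable[Segment], area: StudyArea, buffer_m: float = 10.0
) -> tuple[list[dict], int]:
    """Label each stay with (nearest land-use class, indoor flag).

    Stays whose centroid falls outside the study region are excluded and
    counted. Indoor means the centroid lies within ``buffer_m`` of any
    building footprint.
    """
    stays = list(stays)
    if not stays:
        return [], 0
    cents = [Point(*s.centroid) for s in stays]
    lonlat = [area.projection.to_lonlat(p.x, p.y) for p in cents]
    inside = area.in_region([c[0] for c in lonlat], [c[1] for c in lonlat])
    kept = [s for s, ok in zip(stays, inside) if ok]
    kept_pts = [p for p, ok in zip(cents, inside) if ok]
    n_excluded = int(len(stays) - len(kept))
    if not kept:
        return [], n_excluded
    classes = area.nearest_class(kept_pts)
    indoor = area.near_building(kept_pts, buffer_m)
    out = [
        {"segment": s, "microenv": str(c), "indoor": bool(i)}
        for s, c, i in zip(kept, classes, indoor)
    ]
    return out, n_excluded


def trip_features(seg: Segment) -> dict:
    dx = np.diff(seg.x)
    dy = np.diff(seg.y)
    dt_s = np.diff(seg.minutes) * 60.0
    speeds = np.hypot(dx, dy) / dt_s
    return {
        "mean_speed": float(speeds.mean()),
        "sd_speed": float(speeds.std()),
        "path_length": float(np.hypot(dx, dy).sum()),
    }


def classify_trip_mode(
    trips: Iterable[Segment],
    area: StudyArea,
    speed_threshold: float = 2.5,
    distance_threshold: float = 500.0,
) -> tuple[list[dict], int]:
    """Split trips into vehicle-based and walking-based and label minutes.

    Vehicle when mean speed exceeds the threshold, or the trip is long and
    mean+sd speed exceeds it. Vehicle minutes are ``(vehicle, indoor)``;
    walking minutes are outdoor with the nearest land-use class per minute.
    Single-fix trips carry no speed information and are dropped.
    """
    out: list[dict] = []
    n_dropped = 0
    for seg in trips:
        if len(seg.minutes) < 2:
            n_dropped += 1
            warnings.warn(
                f"{seg.participant_id}: dropping zero-duration trip at minute "
                f"{int(seg.minutes[0])}",
                stacklevel=2,
            )
            continue
        f = trip_features(seg)
        vehicle = f["mean_speed"] > speed_threshold or (
            f["path_length"] > distance_threshold
            and f["mean_speed"] + f["sd_speed"] > speed_threshold
        )
        if vehicle:
            out.append({"segment": seg, "mode": "vehicle",
                        "microenv": np.full(len(seg.minutes), "vehicle", dtype=object),
                        "indoor": True})
        else:
            pts = shapely.points(seg.x, seg.y)
            out.append({"segment": seg, "mode": "walk",
                        "microenv": area.nearest_class(pts), "indoor": False})
    return out, n_dropped


# ---------------------------------------------------------------------------
# Participant-level driver


def identify_context(
    stream: pd.DataFrame, area: StudyArea, params: ContextParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full context identification for a (pre-processed) minute stream.

    Returns per-minute labels (participant_id, timestamp_utc, microenv,
    indoor, segment_id, segment_kind) and a diagnostics dict.
    """
    params = params or ContextParams()
    diags = {"imputed": 0, "unimputable": 0, "stays_out_of_region": 0, "trips_dropped": 0}
    rows = []
    seg_counter = 0
    for pid, part in stream.groupby("participant_id", sort=True, observed=True):
        part = part.sort_values("timestamp_utc")
        ts = pd.DatetimeIndex(part["timestamp_utc"])
        t_min = ((ts.asi8 - ts.asi8[0]) // (60 * 10**9)).astype(np.int64)
        x, y = area.projection.to_xy(part["lon"].to_numpy(), part["lat"].to_numpy())
        x, y = smooth_gps(x, y, params.median_window)
        x, y, imputed, n_imp, n_unimp = impute_gps(t_min, x, y, params.max_gap_min)
        diags["imputed"] += n_imp
        diags["unimputable"] += n_unimp
        have = ~(np.isnan(x) | np.isnan(y))
        segs = detect_stays_trips(
            str(pid), t_min[have], x[have], y[have],
            eps_m=params.eps_m, min_stay_min=params.min_stay_min,
            max_time_gap_min=params.max_time_gap_min,
        )
        t0 = ts.asi8[0]
        minute_to_ts = lambda m: pd.to_datetime(t0 + m * 60 * 10**9, utc=True)

        stay_labels, n_out = assign_stay_context(
            (s for s in segs if s.kind == "stay"), area, params.building_buffer_m
        )
        diags["stays_out_of_region"] += n_out
        trip_labels, n_drop = classify_trip_mode(
            (s for s in segs if s.kind == "trip"), area,
            params.speed_threshold, params.distance_threshold,
        )
        diags["trips_dropped"] += n_drop

        for lab in stay_labels:
            seg = lab["segment"]
            seg_counter += 1
            for m in seg.minutes:
                rows.append((pid, minute_to_ts(int(m)), lab["microenv"], lab["indoor"],
                             f"seg{seg_counter:06d}", "stay"))
        for lab in trip_labels:
            seg = lab["segment"]
            seg_counter += 1
            micro = lab["microenv"]
            for k, m in enumerate(seg.minutes):
                me = micro[k] if isinstance(micro, np.ndarray) else micro
                rows.append((pid, minute_to_ts(int(m)), str(me), lab["indoor"],
                             f"seg{seg_counter:06d}", "trip"))
    labels = pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp_utc", "microenv", "indoor",
                 "segment_id", "segment_kind"],
    )
    if len(labels):
        labels = labels.sort_values(["participant_id", "timestamp_utc"]).reset_index(drop=True)
    return labels, diags


def filter_valid_days(
    labels: pd.DataFrame, min_hours: float = 6.0, timezone: str = "America/Los_Angeles"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participant-days with fewer than ``min_hours`` labelled minutes.

    Days are local-calendar days in the study time zone; the threshold is
    strict (< min_hours drops, exactly min_hours is retained).
    """
    if labels.empty:
        return labels, pd.DataFrame(columns=["participant_id", "day", "minutes"])
    local_day = (
        pd.DatetimeIndex(labels["timestamp_utc"]).tz_convert(timezone).date
    )
    key = pd.DataFrame({
        "participant_id": labels["participant_id"].to_numpy(),
        "day": local_day,
    })
    counts = key.groupby(["participant_id", "day"], observed=True).size()
    bad = counts[counts < min_hours * 60]
    dropped = bad.rename("minutes").reset_index()
    if bad.empty:
        return labels, dropped
    bad_keys = set(bad.index)
    mask = [
        (p, d) not in bad_keys
        for p, d in zip(key["participant_id"].to_numpy(), key["day"].to_numpy())
    ]
    return labels.loc[mask].reset_index(drop=True), dropped


def context_accuracy(labels: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Minute-level (microenvironment, indoor) agreement with ground truth."""
    merged = labels.merge(
        truth[["participant_id", "timestamp_utc", "microenv", "indoor"]],
        on=["participant_id", "timestamp_utc"],
        suffixes=("", "_true"),
    )
    if merged.empty:
        raise ValueError("no overlapping minutes between labels and ground truth")
    ok = (merged["microenv"] == merged["microenv_true"]) & (
        merged["indoor"] == merged["indoor_true"]
    )
    return float(ok.mean())
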