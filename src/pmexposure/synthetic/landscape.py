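"""Synthetic landscape: land-use parcels, building footprints, stations.

The landscape is a regular parcel grid over the interior of the region
polygon. Each parcel carries one of the seven land-use classes (or
``other``); every parcel of an indoor-capable class contains one building
footprint at its centre, while parks stay building-free so outdoor stays are
unambiguous. Regulatory stations are placed inside the region, either at
configured coordinates or at seeded random positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from pmexposure.config import LANDUSE_CLASSES, ConfigError, WorldConfig
from pmexposure.geo import LocalProjection, projection_for, write_geojson

# share of parcels per class; residential dominates as in a metro land base
_CLASS_WEIGHTS = {
    "residential": 0.45,
    "commercial": 0.10,
    "industrial": 0.06,
    "office": 0.10,
    "park_open_space": 0.12,
    "public_facilities": 0.09,
    "other": 0.08,
}
_BUILDING_HALF_M = 8.0  # 16 m square footprints
_HAS_BUILDING = tuple(c for c in LANDUSE_CLASSES if c != "park_open_space")


@dataclass
class Landscape:
    region: Polygon  # lon/lat
    projection: LocalProjection
    parcels: np.ndarray  # shapely polygons in local metres
    parcel_class: np.ndarray  # str per parcel
    buildings: np.ndarray  # shapely polygons in local metres
    stations: pd.DataFrame  # station_id, lon, lat, x, y, decorrelated
    region_xy: Polygon = field(default=None)
    _parcel_tree: STRtree = field(default=None, repr=False)
    _building_tree: STRtree = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.region_xy is None:
            self.region_xy = self.projection.project_geometry(self.region)
        self._parcel_tree = STRtree(list(self.parcels))
        self._building_tree = STRtree(list(self.buildings)) if len(self.buildings) else None

    # -- queries -----------------------------------------------------------
    def nearest_parcel(self, points) -> np.ndarray:
        """Index of the nearest parcel per point; ties -> smallest id."""
        from pmexposure.geo import nearest_with_ties

        return nearest_with_ties(self._parcel_tree, self.parcels, points)

    def nearest_class(self, points) -> np.ndarray:
        idx = self.nearest_parcel(points)
        return self.parcel_class[idx]

    def near_building(self, points, buffer_m: float) -> np.ndarray:
        """True where a point lies within ``buffer_m`` of any building."""
        pts = np.asarray(points, dtype=object)
        out = np.zeros(len(pts), dtype=bool)
        if self._building_tree is None:
            return out
        hit = self._building_tree.query(pts, predicate="dwithin", distance=buffer_m)
        out[np.unique(hit[0])] = True
        return out

    def parcels_of_class(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.parcel_class == cls)

    def parcel_centroid_xy(self, idx: int) -> tuple[float, float]:
        c = self.parcels[idx].centroid
        return c.x, c.y

    # -- serialization -----------------------------------------------------
    def landuse_features(self):
        for poly, cls in zip(self.parcels, self.parcel_class):
            yield self.projection.unproject_geometry(poly), {"class": str(cls)}

    def building_features(self):
        for poly in self.buildings:
            yield self.projection.unproject_geometry(poly), {}

    def write(self, outdir) -> list[str]:
        write_geojson(f"{outdir}/landuse.geojson", self.landuse_features())
        write_geojson(f"{outdir}/buildings.geojson", self.building_features())
        write_geojson(f"{outdir}/region.geojson", [(self.region, {})])
        self.stations[["station_id", "lat", "lon"]].to_csv(
            f"{outdir}/station_sites.csv", index=False, float_format="%.6f"
        )
        return ["landuse.geojson", "buildings.geojson", "region.geojson", "station_sites.csv"]


def generate_landscape(config: WorldConfig) -> Landscape:
    region = config.region_polygon()
    if region.area <= 0:
        raise ConfigError("region polygon has zero area")
    proj = projection_for(region)
    region_xy = proj.project_geometry(region)
    rng = np.random.default_rng([config.seed, 1])

    minx, miny, maxx, maxy = region_xy.bounds
    size = config.parcel_size_m
    # inset half a parcel so parcels sit fully inside rectangular regions
    xs = np.arange(minx + size / 2, maxx - size / 2, size)
    ys = np.arange(miny + size / 2, maxy - size / 2, size)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    # leave interstitial gaps so parcels tile a subset of the region
    half = size * 0.46
    keep = shapely.contains(region_xy, shapely.points(gx, gy))
    gx, gy = gx[keep], gy[keep]
    if len(gx) == 0:
        raise ConfigError("region too small for a single parcel")
    parcels = shapely.box(gx - half, gy - half, gx + half, gy + half)

    classes = np.array(list(_CLASS_WEIGHTS), dtype=object)
    weights = np.array(list(_CLASS_WEIGHTS.values()))
    parcel_class = rng.choice(classes, size=len(parcels), p=weights / weights.sum())
    # guarantee every class appears at least once
    for k, cls in enumerate(classes):
        if not (parcel_class == cls).any():
            parcel_class[k % len(parcel_class)] = cls

    has_b = np.isin(parcel_class, _HAS_BUILDING)
    bx, by = gx[has_b], gy[has_b]
    buildings = shapely.box(
        bx - _BUILDING_HALF_M, by - _BUILDING_HALF_M, bx + _BUILDING_HALF_M, by + _BUILDING_HALF_M
    )

    if config.station_positions is not None:
        lonlat = np.asarray(config.station_positions, dtype=float)
        sx, sy = proj.to_xy(lonlat[:, 0], lonlat[:, 1])
        slon, slat = lonlat[:, 0], lonlat[:, 1]
    else:
        # jittered grid: quasi-uniform coverage like a regulatory network
        n = config.n_stations
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        exs = np.linspace(minx + size, maxx - size, ncol + 2)[1:-1]
        eys = np.linspace(miny + size, maxy - size, nrow + 2)[1:-1]
        ggx, ggy = np.meshgrid(exs, eys)
        order = rng.permutation(ggx.size)[:n]
        jit = 0.1 * min(maxx - minx, maxy - miny)
        sx = ggx.ravel()[order] + rng.uniform(-jit, jit, n)
        sy = ggy.ravel()[order] + rng.uniform(-jit, jit, n)
        slon, slat = proj.to_lonlat(sx, sy)
    inside = shapely.contains(region_xy, shapely.points(np.atleast_1d(sx), np.atleast_1d(sy)))
    if not inside.all():
        raise ConfigError("station position(s) outside region polygon")
    decor = config.station_decorrelated
    if decor is None:
        decor = [False] * len(np.atleast_1d(sx))
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i:03d}" for i in range(len(np.atleast_1d(sx)))],
            "lon": np.atleast_1d(slon),
            "lat": np.atleast_1d(slat),
            "x": np.atleast_1d(sx),
            "y": np.atleast_1d(sy),
            "decorrelated": list(decor),
        }
    )

    return Landscape(
        region=region,
        projection=proj,
        parcels=np.asarray(parcels, dtype=object),
        parcel_class=parcel_class.astype(object),
        buildings=np.asarray(buildings, dtype=object),
        stations=stations,
        region_xy=region_xy,
    )
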