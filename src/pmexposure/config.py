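"""Configuration objects for the simulation and the processing pipeline.

Every tunable that the processing stages use is named here with its default,
so a run is fully described by one declarative config (YAML) plus a seed.
Unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import yaml
from shapely.geometry import Polygon, shape

LANDUSE_CLASSES = (
    "commercial",
    "industrial",
    "office",
    "park_open_space",
    "public_facilities",
    "residential",
    "other",
)
#: Microenvironment vocabulary = the seven land-use classes plus vehicle.
MICROENVIRONMENTS = LANDUSE_CLASSES + ("vehicle",)


class ConfigError(ValueError):
    pass


def _default_region() -> list[tuple[float, float]]:
    # ~22 x 22 km box around central Puget Sound
    lon0, lat0, dlon, dlat = -122.33, 47.61, 0.145, 0.098
    return [
        (lon0 - dlon, lat0 - dlat),
        (lon0 + dlon, lat0 - dlat),
        (lon0 + dlon, lat0 + dlat),
        (lon0 - dlon, lat0 + dlat),
    ]


@dataclass
class WorldConfig:
    """Ground-truth world: landscape, behaviour, pollution, and sensor model.

    Defaults describe the emulated study: a ~160-person cohort each wearing a
    1-min personal monitor for two weeks, with a known linear sensor
    distortion (reference = slope * raw + intercept) and indoor sources
    (cooking around dinnertime, heating in winter) on top of an ambient
    background with winter and evening maxima.
    """

    seed: int = 0
    n_participants: int = 160
    n_days: int = 14
    region: Sequence[tuple[float, float]] = field(default_factory=_default_region)
    n_stations: int = 12
    gps_noise_sd: float = 10.0  # metres
    gps_gap_rate: float = 0.02  # probability a minute's fix is dropped
    sensor_slope: float = 0.5  # reference = slope*raw + intercept
    sensor_intercept: float = 2.0  # ug/m3
    sensor_noise_sd: float = 0.05  # lognormal sigma on raw, 0 disables
    indoor_infiltration: float = 0.6  # fraction of ambient reaching indoors
    cooking_peak_hour: int = 19  # local hour of the dinnertime source peak
    cooking_peak_ug: float = 20.0  # median peak amplitude, ug/m3
    cooking_prob: float = 0.8  # probability of a cooking event per home-day
    winter_heating_boost: float = 3.0  # ug/m3 added indoors Dec-Feb
    breathing_rate: float = 0.012  # m3/min, constant
    indoor_target: float = 0.78  # target fraction of time indoors
    residential_target: float = 0.67  # target fraction of time in residences
    # Ambient field: A0 + As*cos(2*pi*doy/365) + Ad*cos(2*pi*(hour-19)/24) + AR(1)
    ambient_base: float = 8.0
    ambient_seasonal_amp: float = 3.0
    ambient_diurnal_amp: float = 2.0
    ambient_ar_phi: float = 0.8
    ambient_ar_sd: float = 1.0  # innovation sd; 0 disables ambient noise
    walk_speed: float = 1.4  # m/s
    vehicle_speed: float = 12.0  # m/s
    parcel_size_m: float = 250.0
    study_start: str = "2019-01-01"  # first possible local monitoring day
    stagger_days: int = 350  # participant start days drawn in [0, stagger_days]
    timezone: str = "America/Los_Angeles"
    zero_sensor_participants: int = 0  # participants emitting all-zero channels
    station_positions: Optional[Sequence[tuple[float, float]]] = None  # lon/lat
    station_decorrelated: Optional[Sequence[bool]] = None
    home_anchor_points: Optional[Sequence[tuple[float, float]]] = None  # lon/lat

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (0.0 <= self.gps_gap_rate < 1.0):
            raise ConfigError("gps_gap_rate must be in [0, 1)")
        if not (0.0 < self.indoor_infiltration <= 1.0):
            raise ConfigError("indoor_infiltration must be in (0, 1]")
        if self.sensor_slope == 0:
            raise ConfigError("sensor_slope must be nonzero")
        if self.region_polygon().area <= 0:
            raise ConfigError("region polygon has zero area")
        if self.n_stations < 1 and not self.station_positions:
            raise ConfigError("need at least one station")

    def region_polygon(self) -> Polygon:
        if isinstance(self.region, dict):  # GeoJSON geometry
            return shape(self.region)
        return Polygon(self.region)

    @property
    def landuse_classes(self) -> tuple[str, ...]:
        return LANDUSE_CLASSES


@dataclass
class ContextParams:
    """Trajectory smoothing, segmentation, and labelling parameters."""

    median_window: int = 5  # odd, fixes
    max_gap_min: int = 10  # longest imputable GPS gap
    eps_m: float = 30.0  # stay cluster radius
    min_stay_min: int = 5  # minimum stay duration
    max_time_gap_min: int = 10  # contiguity break
    speed_threshold: float = 2.5  # m/s, vehicle vs walk
    distance_threshold: float = 500.0  # m, trip length rule
    building_buffer_m: float = 10.0  # indoor if stay centroid within this
    min_valid_hours: float = 6.0  # valid participant-day threshold
    timezone: str = "America/Los_Angeles"

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigError("median_window must be odd and >= 3")


@dataclass
class CalibrationParams:
    """In-situ calibration against regulatory stations."""

    cutoff_grid_km: Sequence[float] = (0.5, 0.6, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    min_outdoor_minutes: int = 30  # support behind each hourly pair
    min_pairs: int = 50
    covariates: Sequence[str] = ("rh", "temp")

    def __post_init__(self) -> None:
        if len(self.cutoff_grid_km) == 0:
            raise ConfigError("cutoff grid must be non-empty")


@dataclass
class ExposureParams:
    idw_power: float = 2.0
    idw_max_radius_km: float = 50.0
    breathing_rate: float = 0.012  # m3/min


@dataclass
class RunConfig:
    """One end-to-end run: paths plus all stage parameters."""

    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    context: ContextParams = field(default_factory=ContextParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    exposure: ExposureParams = field(default_factory=ExposureParams)
    verbose: bool = False


def _from_mapping(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    nested = {
        "world": WorldConfig,
        "context": ContextParams,
        "calibration": CalibrationParams,
        "exposure": ExposureParams,
    }
    kwargs: dict[str, Any] = {}
    for key, val in doc.items():
        if key in nested:
            kwargs[key] = _from_mapping(nested[key], val or {})
        elif key in {"seed", "verbose"}:
            kwargs[key] = val
        else:
            raise ConfigError(f"unknown RunConfig key: {key}")
    return RunConfig(**kwargs)


def dump_run_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
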