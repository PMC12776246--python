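"""Readers, writers and run configuration.

Every external representation the suite touches crosses this boundary with
validation: NetCDF for gridded fields (velocity, masks, density), CSV for
point tables and reports, HURDAT2 text for storm tracks, YAML for run
configuration.  Longitudes are stored in [-180, 180], latitudes in
[-90, 90], grids ascending; unknown configuration keys are rejected rather
than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .domain import DomainSpec, GridMask, HABITAT_NAMES
from .lagrangian_tracker import ALLOWED_MAX_FLOATS, VelocityField

NETCDF_ENGINE = "scipy"


class BoundaryError(ValueError):
    """A file failed validation at the IO boundary."""


# --------------------------------------------------------------------------
# NetCDF: velocity, mask, density
# --------------------------------------------------------------------------

def write_velocity_netcdf(field_: VelocityField, path) -> None:
    spec = field_.spec
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), field_.u, {"units": "m/s"}),
            "v": (("time", "lat", "lon"), field_.v, {"units": "m/s"}),
            "node_valid": (("lat", "lon"), field_.node_valid.astype(np.int8)),
        },
        coords={"time": spec.times, "lat": spec.lat_edges, "lon": spec.lon_edges},
        attrs={
            "resolution_deg": spec.resolution,
            "lon_min": spec.lon_min,
            "lon_max": spec.lon_max,
            "lat_min": spec.lat_min,
            "lat_max": spec.lat_max,
            "grid": "node (cell-corner) values",
        },
    )
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def read_velocity_netcdf(path) -> VelocityField:
    """Load and validate an hourly node-lattice velocity file."""
    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        ds = ds.load()
    for var in ("u", "v"):
        if var not in ds:
            raise BoundaryError(f"velocity file missing variable {var!r}")
        if ds[var].attrs.get("units") not in ("m/s", "m s-1"):
            raise BoundaryError(f"variable {var!r} must declare units of m/s")
        if tuple(ds[var].dims) != ("time", "lat", "lon"):
            raise BoundaryError(f"variable {var!r} must have dims (time, lat, lon)")
    times = pd.to_datetime(ds["time"].values)
    if len(times) > 1:
        steps = np.diff(times.values) / np.timedelta64(1, "h")
        if not np.allclose(steps, 1.0):
            raise BoundaryError("time coordinate must be hourly")
    res = float(ds.attrs["resolution_deg"])
    spec = DomainSpec(
        lon_min=float(ds.attrs["lon_min"]),
        lon_max=float(ds.attrs["lon_max"]),
        lat_min=float(ds.attrs["lat_min"]),
        lat_max=float(ds.attrs["lat_max"]),
        resolution=res,
        t0=np.datetime64(times[0]),
        n_hours=len(times),
    )
    node_valid = ds["node_valid"].values.astype(bool) if "node_valid" in ds else None
    return VelocityField(spec, ds["u"].values, ds["v"].values, node_valid=node_valid)


def write_mask_netcdf(mask: GridMask, path) -> None:
    spec = mask.spec
    import json

    ds = xr.Dataset(
        {
            "land": (("lat", "lon"), mask.land.astype(np.int8)),
            "habitat": (("lat", "lon"), mask.habitat.astype(np.int8)),
            "lagoon_id": (("lat", "lon"), mask.lagoon_id.astype(np.int16)),
        },
        coords={"lat": spec.lat_centers, "lon": spec.lon_centers},
        attrs={
            "resolution_deg": spec.resolution,
            "lon_min": spec.lon_min,
            "lon_max": spec.lon_max,
            "lat_min": spec.lat_min,
            "lat_max": spec.lat_max,
            "t0": str(spec.t0),
            "n_hours": spec.n_hours,
            "habitat_codes": json.dumps({str(k): v for k, v in HABITAT_NAMES.items()}),
            "waterbodies": json.dumps(mask.waterbodies),
        },
    )
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def read_mask_netcdf(path) -> GridMask:
    import json

    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        ds = ds.load()
    for var in ("land", "habitat", "lagoon_id"):
        if var not in ds:
            raise BoundaryError(f"mask file missing variable {var!r}")
    spec = DomainSpec(
        lon_min=float(ds.attrs["lon_min"]),
        lon_max=float(ds.attrs["lon_max"]),
        lat_min=float(ds.attrs["lat_min"]),
        lat_max=float(ds.attrs["lat_max"]),
        resolution=float(ds.attrs["resolution_deg"]),
        t0=np.datetime64(str(ds.attrs["t0"])),
        n_hours=int(ds.attrs["n_hours"]),
    )
    waterbodies = {k: tuple(v) for k, v in json.loads(ds.attrs["waterbodies"]).items()}
    return GridMask(
        spec,
        ds["land"].values.astype(bool),
        ds["habitat"].values.astype(np.int8),
        ds["lagoon_id"].values.astype(np.int16),
        waterbodies,
    )


def write_density_netcdf(density: np.ndarray, spec: DomainSpec, path) -> None:
    xr.Dataset(
        {"trajectory_count": (("lat", "lon"), density.astype(np.int64))},
        coords={"lat": spec.lat_centers, "lon": spec.lon_centers},
        attrs={"description": "distinct trajectories intersecting each cell"},
    ).to_netcdf(path, engine=NETCDF_ENGINE)


# --------------------------------------------------------------------------
# point-table CSV
# --------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ("id", "lon", "lat", "habitat", "EMT", "MAP", "SST", "waterbody_id")


def write_points_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_points_csv(path, required=OCCURRENCE_COLUMNS):
    """Load an occurrence table; range-failing rows go to a rejects report.

    Returns ``(table, rejects)``; a missing mandatory column or duplicated
    id aborts the load instead.
    """
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BoundaryError(f"missing mandatory columns: {missing}")
    if df["id"].duplicated().any():
        raise BoundaryError("duplicated record ids")
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[~df["lat"].between(-90, 90)] = "latitude outside [-90, 90]"
    reasons[~df["lon"].between(-180, 180)] = "longitude outside [-180, 180]"
    reasons[df["MAP"].notna() & (df["MAP"] < 0)] = "negative MAP"
    reasons[~df["habitat"].isin([0, 1])] = "habitat not binary"
    bad = reasons != ""
    rejects = df[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    table = df[~bad].reset_index(drop=True)
    if "waterbody_id" in table.columns:
        table["waterbody_id"] = table["waterbody_id"].fillna("").astype(str)
    return table, rejects


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SDMSettings:
    n_occurrences: int = 2000
    train_frac: float = 0.70
    reps: int = 10
    tss_min: float = 0.8
    criteria: tuple = ("maxTSS", "maxKappa", "sens=spec", "prevalence", "minROCdist", "fixed-0.5")

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class TrackerSettings:
    max_float_months: float = 1
    min_float_days: tuple = (1.0, 5.0)
    window_start: str = "2011-08-01T00:00"
    window_hours: int = 24
    n_source_points: int = 8
    velocity_kind: str = "coastal_jet_tidal"
    velocity_params: dict = field(
        default_factory=lambda: {
            "jet_u": 0.0,
            "jet_v": 0.35,
            "tidal_amplitude": 0.08,
            "tidal_period_hours": 12.0,
            "reversal_time": None,
        }
    )
    allow_any_max_float: bool = False

    def __post_init__(self):
        if not self.allow_any_max_float and self.max_float_months not in ALLOWED_MAX_FLOATS:
            raise ValueError(
                f"max_float_months must be one of {ALLOWED_MAX_FLOATS} "
                "(set allow_any_max_float to override)"
            )
        lo, hi = self.min_float_days
        if not 0 < lo <= hi:
            raise ValueError("min_float_days must be an increasing positive pair")


@dataclass(frozen=True)
class HurricaneSettings:
    months: tuple = (8, 9, 10)
    sectors: int = 16
    region_box: tuple = (-82.0, 24.0, -79.0, 31.0)
    n_tracks: int = 12
    years: tuple | None = None


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    domain: dict = field(
        default_factory=lambda: {
            "lon_min": -81.5,
            "lon_max": -78.0,
            "lat_min": 24.0,
            "lat_max": 35.0,
            "resolution": 1.0 / 8.0,
            "t0": "2011-08-01T00:00",
        }
    )
    sdm: SDMSettings = field(default_factory=SDMSettings)
    tracker: TrackerSettings = field(default_factory=TrackerSettings)
    subregions: tuple = (
        ("SFL", 24.5, 26.5),
        ("CFL1", 26.5, 28.0),
        ("CFL2", 28.0, 29.0),
        ("NFL", 29.0, 30.7),
        ("GA", 30.7, 32.0),
    )
    regions: dict = field(
        default_factory=lambda: {"east_florida": (24.5, 30.7), "georgia": (30.7, 32.0)}
    )
    bin_width: float = 0.1
    hurricanes: HurricaneSettings = field(default_factory=HurricaneSettings)

    def domain_spec(self, n_hours: int | None = None) -> DomainSpec:
        d = self.domain
        if n_hours is None:
            from .lagrangian_tracker import DAYS_PER_MONTH

            n_hours = (
                self.tracker.window_hours
                + int(round(self.tracker.max_float_months * DAYS_PER_MONTH * 24))
                + 2
            )
        return DomainSpec(
            lon_min=float(d["lon_min"]),
            lon_max=float(d["lon_max"]),
            lat_min=float(d["lat_min"]),
            lat_max=float(d["lat_max"]),
            resolution=float(d.get("resolution", 1.0 / 8.0)),
            t0=np.datetime64(str(d.get("t0", "2011-08-01T00:00"))),
            n_hours=int(n_hours),
        )


def _merge_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise BoundaryError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; absent keys take defaults, unknown
    keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise BoundaryError("config root must be a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise BoundaryError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "domain" in raw:
        base = RunConfig().domain
        extra = set(raw["domain"]) - set(base)
        if extra:
            raise BoundaryError(f"unknown key(s) in config section 'domain': {sorted(extra)}")
        base.update(raw["domain"])
        kwargs["domain"] = base
    if "sdm" in raw:
        kwargs["sdm"] = _merge_section(SDMSettings, raw["sdm"], "sdm")
    if "tracker" in raw:
        kwargs["tracker"] = _merge_section(TrackerSettings, raw["tracker"], "tracker")
    if "hurricanes" in raw:
        kwargs["hurricanes"] = _merge_section(HurricaneSettings, raw["hurricanes"], "hurricanes")
    if "subregions" in raw:
        kwargs["subregions"] = tuple(tuple(s) for s in raw["subregions"])
    if "regions" in raw:
        kwargs["regions"] = {k: tuple(v) for k, v in raw["regions"].items()}
    if "bin_width" in raw:
        kwargs["bin_width"] = float(raw["bin_width"])
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    """Echo the resolved configuration next to the outputs, for provenance."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(plain(config), fh, sort_keys=True)
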