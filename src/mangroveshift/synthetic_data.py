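"""Synthetic inputs with known ground truth for the whole pipeline.

The real analysis consumes wetland occurrence polygons, downscaled climate
rasters, an eddy- and tide-resolving ocean simulation, and the NHC best-track
archive.  None of those are redistributable at desk scale, so this module
fabricates each input class with analytically known structure:

* a meridional mainland coast with at least one barrier-enclosed lagoon
  (reachable only through its inlet cells) and urban beach segments;
* velocity fields with closed-form trajectories (uniform flow, the classic
  steady double gyre, and an alongshore jet with seasonal reversal plus a
  zero-mean tidal sinusoid);
* presence/absence occurrence records drawn from a stated logistic model on
  a latitudinal extreme-minimum-temperature (EMT) gradient, with a
  sea-surface-temperature (SST) covariate deliberately collinear with EMT;
* storm-track files in the HURDAT2 second-generation text dialect.

Because every generator is seeded and its truth parameters are explicit,
downstream estimates (logistic coefficients, stranding statistics, wind-rose
frequencies) can be checked against what was put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from .domain import (
    EARTH_RADIUS_M,
    HABITAT_INLET,
    HABITAT_MANGROVE,
    HABITAT_SALTMARSH,
    HABITAT_URBAN,
    DomainSpec,
    GridMask,
    coastal_cells,
    substream,
)
from .hurricane_analysis import Fix, StormTrack, serialize_hurdat2
from .lagrangian_tracker import VelocityField, mask_field_nodes

#: CMIP6 scenario names, ordered by severity.
SCENARIOS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")


# --------------------------------------------------------------------------
# coastline / land mask
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LagoonSpec:
    """A lagoon strip between the mainland and a barrier island.

    The barrier column is land over ``[lat_min, lat_max)`` except at the
    inlet latitudes, and the strip is capped by land rows at both ends, so
    the enclosed water communicates with the open ocean only through the
    inlet cells.
    """

    barrier_lon: float
    lat_min: float
    lat_max: float
    inlet_lats: tuple = ()

    def __post_init__(self):
        if self.lat_min >= self.lat_max:
            raise ValueError("lagoon latitude range must be non-empty")
        if len(self.inlet_lats) < 1:
            raise ValueError("a lagoon needs at least one inlet")


@dataclass(frozen=True)
class CoastlineParams:
    """Declarative coastline: mainland edge, lagoons, urban beach segments."""

    coast_lon: float
    ecotone_lat: float
    lagoons: tuple = ()
    urban_segments: tuple = ()  # (lat_min, lat_max) pairs on the open coast


def default_coastline_params(spec: DomainSpec) -> CoastlineParams:
    """One lagoon with a single inlet plus one urban beach segment."""
    width = spec.lon_max - spec.lon_min
    span = spec.lat_max - spec.lat_min
    coast_lon = spec.lon_min + 0.3 * width
    lag_lat0 = spec.lat_min + 0.35 * span
    lag_lat1 = lag_lat0 + max(0.15 * span, 4 * spec.resolution)
    return CoastlineParams(
        coast_lon=coast_lon,
        ecotone_lat=spec.lat_min + 0.45 * span,
        lagoons=(
            LagoonSpec(
                barrier_lon=coast_lon + 3.5 * spec.resolution,
                lat_min=lag_lat0,
                lat_max=lag_lat1,
                inlet_lats=(0.5 * (lag_lat0 + lag_lat1),),
            ),
        ),
        urban_segments=((spec.lat_min + 0.1 * span, spec.lat_min + 0.18 * span),),
    )


def make_land_mask(spec: DomainSpec, params: CoastlineParams) -> GridMask:
    """Build the land/ocean/habitat grid from declarative coastline params.

    Land lies west of ``coast_lon``.  Coastal ocean cells carry a habitat
    class: mangrove south of the ecotone latitude, salt marsh north of it,
    with inlet and urban overrides.
    """
    lonc = spec.lon_centers
    latc = spec.lat_centers
    land = np.zeros((spec.n_lat, spec.n_lon), dtype=bool)
    land[:, lonc < params.coast_lon] = True

    lagoon_id = np.zeros_like(land, dtype=np.int16)
    waterbodies: dict = {}
    for k, lg in enumerate(params.lagoons, start=1):
        bcol = int(np.floor((lg.barrier_lon - spec.lon_min) / spec.resolution))
        if not (0 <= bcol < spec.n_lon) or lonc[bcol] <= params.coast_lon:
            raise ValueError("lagoon barrier must lie east of the coast, inside the domain")
        in_range = (latc >= lg.lat_min) & (latc < lg.lat_max)
        rows = np.where(in_range)[0]
        if len(rows) == 0:
            raise ValueError("lagoon latitude range contains no grid rows")
        land[rows, bcol] = True
        inlet_rows = []
        for ilat in lg.inlet_lats:
            r = int(np.floor((ilat - spec.lat_min) / spec.resolution))
            if r not in rows:
                raise ValueError("inlet latitude outside the lagoon's range")
            land[r, bcol] = False
            inlet_rows.append(r)
        # end caps seal the strip between the mainland and the barrier
        strip = (lonc >= params.coast_lon) & (lonc < lg.barrier_lon)
        for cap in (rows[0] - 1, rows[-1] + 1):
            if 0 <= cap < spec.n_lat:
                land[cap, strip] = True
                land[cap, bcol] = True
        lag_cells = np.zeros_like(land)
        lag_cells[np.ix_(rows, np.where(strip)[0])] = True
        lagoon_id[lag_cells & ~land] = k
        waterbodies[f"lagoon_{k}"] = (float(lonc[bcol]), float(latc[inlet_rows[0]]))

    if land.all() or (~land).all():
        raise ValueError("degenerate coastline: all land or all ocean")

    coastal = coastal_cells(land)
    habitat = np.zeros_like(land, dtype=np.int8)
    south = latc[:, None] < params.ecotone_lat
    habitat[coastal & south] = HABITAT_MANGROVE
    habitat[coastal & ~south] = HABITAT_SALTMARSH
    for lat0, lat1 in params.urban_segments:
        seg = coastal & ((latc[:, None] >= lat0) & (latc[:, None] < lat1)) & (lagoon_id == 0)
        habitat[seg] = HABITAT_URBAN
    for k, lg in enumerate(params.lagoons, start=1):
        for ilat in lg.inlet_lats:
            r = int(np.floor((ilat - spec.lat_min) / spec.resolution))
            bcol = int(np.floor((lg.barrier_lon - spec.lon_min) / spec.resolution))
            habitat[r, bcol] = HABITAT_INLET

    return GridMask(spec, land, habitat, lagoon_id, waterbodies)


# --------------------------------------------------------------------------
# velocity fields
# --------------------------------------------------------------------------

def make_velocity_field(kind: str, params: dict, spec: DomainSpec, mask: GridMask | None = None) -> VelocityField:
    """Analytic hourly velocity field.

    kinds
    -----
    ``uniform``
        constant ``(u, v)`` m/s everywhere.
    ``double_gyre``
        steady two-cell flow ``u = -U sin(pi x) cos(pi y)``,
        ``v = U cos(pi x) sin(pi y)`` with ``x in [0, 2]``, ``y in [0, 1]``
        mapped onto the domain; the normal velocity vanishes on every
        boundary.
    ``coastal_jet_tidal``
        spatially uniform alongshore jet ``(jet_u, jet_v)`` whose sign flips
        at ``reversal_time``, plus a zero-mean tidal sinusoid of amplitude
        ``tidal_amplitude`` (m/s) and period ``tidal_period_hours`` added to
        the zonal component.
    """
    nt, nlat, nlon = spec.n_hours, spec.n_lat + 1, spec.n_lon + 1
    hours = np.arange(nt, dtype=float)

    if kind == "uniform":
        u = np.full((nt, nlat, nlon), float(params["u"]))
        v = np.full((nt, nlat, nlon), float(params["v"]))
    elif kind == "double_gyre":
        U = float(params.get("max_speed", 0.5))
        x = 2.0 * (spec.lon_edges - spec.lon_min) / (spec.lon_max - spec.lon_min)
        y = (spec.lat_edges - spec.lat_min) / (spec.lat_max - spec.lat_min)
        X, Y = np.meshgrid(x, y)
        u0 = -U * np.sin(np.pi * X) * np.cos(np.pi * Y)
        v0 = U * np.cos(np.pi * X) * np.sin(np.pi * Y)
        u = np.broadcast_to(u0, (nt, nlat, nlon)).copy()
        v = np.broadcast_to(v0, (nt, nlat, nlon)).copy()
    elif kind == "coastal_jet_tidal":
        jet_u = float(params.get("jet_u", 0.0))
        jet_v = float(params.get("jet_v", 0.3))
        amp = float(params.get("tidal_amplitude", 0.1))
        period = float(params.get("tidal_period_hours", 12.0))
        reversal = params.get("reversal_time")
        sign = np.ones(nt)
        if reversal is not None:
            rev_h = (np.datetime64(reversal) - spec.t0) / np.timedelta64(1, "h")
            sign[hours >= float(rev_h)] = -1.0
        tidal = amp * np.sin(2.0 * np.pi * hours / period)
        u = (sign * jet_u + tidal)[:, None, None] * np.ones((1, nlat, nlon))
        v = (sign * jet_v)[:, None, None] * np.ones((1, nlat, nlon))
    else:
        raise ValueError(f"unknown velocity field kind: {kind!r}")

    fld = VelocityField(spec, u, v)
    if mask is not None:
        fld = mask_field_nodes(fld, mask)
    return fld


def double_gyre_stream_function(spec: DomainSpec, lon, lat, max_speed: float = 0.5):
    """Stream function of the steady double gyre (same scaling as the field).

    In the mapped (x, y) coordinates the flow is Hamiltonian with
    ``psi = -(U/pi) sin(pi x) sin(pi y) * scale_y`` up to the anisotropic
    degree metric; useful as a conservation oracle on near-equatorial test
    domains where the metric is close to isotropic.
    """
    x = 2.0 * (np.asarray(lon, dtype=float) - spec.lon_min) / (spec.lon_max - spec.lon_min)
    y = (np.asarray(lat, dtype=float) - spec.lat_min) / (spec.lat_max - spec.lat_min)
    return np.sin(np.pi * x) * np.sin(np.pi * y)


# --------------------------------------------------------------------------
# occurrence data + climate truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind the synthetic occurrence data.

    The presence probability is ``logistic(b0 + b_emt*EMT + b_map*MAP)``;
    EMT (degC) falls linearly with latitude at ``emt_lapse`` degC per degree
    from ``emt_at_south`` at the domain's southern edge; SST is coupled to
    EMT as ``sst_slope * EMT + sst_intercept + N(0, sst_noise_sd)``, making
    the two strongly collinear by construction.
    """

    b0: float = -6.0
    b_emt: float = 3.0
    b_map: float = 0.001
    emt_at_south: float = 6.0
    emt_lapse: float = 1.2
    sst_slope: float = 0.8
    sst_intercept: float = 22.0
    sst_noise_sd: float = 0.5
    map_range: tuple = (900.0, 1600.0)
    lagoon_fraction: float = 0.15
    scenario_emt_offsets: dict = dc_field(
        default_factory=lambda: {
            "SSP1-2.6": 1.5,
            "SSP2-4.5": 2.5,
            "SSP3-7.0": 3.5,
            "SSP5-8.5": 5.0,
        }
    )
    scenario_map_factors: dict = dc_field(
        default_factory=lambda: {
            "SSP1-2.6": 1.0,
            "SSP2-4.5": 1.02,
            "SSP3-7.0": 1.03,
            "SSP5-8.5": 1.05,
        }
    )

    def __post_init__(self):
        offs = [self.scenario_emt_offsets[s] for s in SCENARIOS]
        if not all(a <= b for a, b in zip(offs, offs[1:])):
            raise ValueError("scenario EMT offsets must be non-decreasing with severity")
        if not 0.0 <= self.lagoon_fraction < 1.0:
            raise ValueError("lagoon_fraction must be in [0, 1)")

    def emt_at(self, lat, lat_south):
        return self.emt_at_south - self.emt_lapse * (np.asarray(lat, dtype=float) - lat_south)


def make_occurrence_dataset(
    spec: DomainSpec,
    truth: SyntheticTruth,
    n: int,
    seed: int,
    mask: GridMask | None = None,
) -> pd.DataFrame:
    """Presence/absence records on coastal cells with climate covariates.

    A ``lagoon_fraction`` share of records sits inside lagoons with SST
    withheld (the coarse SST product does not resolve enclosed waterbodies),
    carrying a ``waterbody_id`` instead; these exercise the inlet-fill path
    of the covariate preparation stage.
    """
    if n < 50:
        raise ValueError("n must be >= 50 (cross-validation needs both classes)")
    if mask is None:
        mask = make_land_mask(spec, default_coastline_params(spec))
    rng = substream(seed, "occurrence")

    coastal = mask.coastal & (mask.lagoon_id == 0)
    lagoon = (mask.lagoon_id > 0) & ~mask.land
    open_cells = np.argwhere(coastal)
    lagoon_cells = np.argwhere(lagoon)
    n_lagoon = int(round(truth.lagoon_fraction * n)) if len(lagoon_cells) else 0

    pick_open = open_cells[rng.integers(0, len(open_cells), size=n - n_lagoon)]
    pick_lag = (
        lagoon_cells[rng.integers(0, len(lagoon_cells), size=n_lagoon)]
        if n_lagoon
        else np.empty((0, 2), dtype=int)
    )
    cells = np.vstack([pick_open, pick_lag])
    is_lagoon = np.zeros(n, dtype=bool)
    is_lagoon[n - n_lagoon :] = True

    jitter = rng.uniform(0.0, 1.0, size=(n, 2)) - 0.5
    lon = spec.lon_centers[cells[:, 1]] + jitter[:, 0] * spec.resolution * 0.9
    lat = spec.lat_centers[cells[:, 0]] + jitter[:, 1] * spec.resolution * 0.9

    emt = truth.emt_at(lat, spec.lat_min)
    map_ = rng.uniform(*truth.map_range, size=n)
    sst = truth.sst_slope * emt + truth.sst_intercept + rng.normal(0.0, truth.sst_noise_sd, size=n)
    p = expit(truth.b0 + truth.b_emt * emt + truth.b_map * map_)
    habitat = (rng.uniform(size=n) < p).astype(int)

    wid = np.array(
        [
            f"lagoon_{int(mask.lagoon_id[r, c])}" if is_lagoon[i] else ""
            for i, (r, c) in enumerate(cells)
        ],
        dtype=object,
    )
    sst = np.where(is_lagoon, np.nan, sst)

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "lon": lon,
            "lat": lat,
            "habitat": habitat,
            "EMT": emt,
            "MAP": map_,
            "SST": sst,
            "waterbody_id": wid,
        }
    )
    return table


def make_climate_raster(spec: DomainSpec, truth: SyntheticTruth, mask: GridMask) -> xr.Dataset:
    """Gridded EMT/MAP/SST analogs on cell centres.

    SST is defined on open-ocean cells only (missing over land and inside
    lagoons, mirroring the resolution limits of the real SST product).
    """
    latc, lonc = spec.lat_centers, spec.lon_centers
    emt = np.broadcast_to(truth.emt_at(latc, spec.lat_min)[:, None], (spec.n_lat, spec.n_lon)).copy()
    lo, hi = truth.map_range
    map_ = (
        0.5 * (lo + hi)
        + 0.25 * (hi - lo) * np.sin(2 * np.pi * (latc[:, None] - spec.lat_min) / (spec.lat_max - spec.lat_min))
        + 0.0 * lonc[None, :]
    )
    sst = truth.sst_slope * emt + truth.sst_intercept
    sst = np.where(mask.land | (mask.lagoon_id > 0), np.nan, sst)
    return xr.Dataset(
        {
            "emt": (("lat", "lon"), emt),
            "map": (("lat", "lon"), map_),
            "sst": (("lat", "lon"), sst),
        },
        coords={"lat": latc, "lon": lonc},
        attrs={
            "emt_units": "degC",
            "map_units": "mm/yr",
            "sst_units": "degC",
            "sst_slope": truth.sst_slope,
        },
    )


def make_future_climate(raster: xr.Dataset, offsets_per_scenario: dict, map_factors: dict | None = None) -> dict:
    """Scenario rasters: EMT shifted additively, MAP scaled multiplicatively.

    SST warms with EMT through the coupling slope recorded in the raster
    attrs when present (additive ``sst_slope * offset``); geometry unchanged.
    """
    missing = [s for s in SCENARIOS if s not in offsets_per_scenario]
    if missing:
        raise ValueError(f"missing scenario offsets for: {missing}")
    out = {}
    slope = float(raster.attrs.get("sst_slope", 0.0))
    for s in SCENARIOS:
        off = float(offsets_per_scenario[s])
        fac = float(map_factors[s]) if map_factors else 1.0
        ds = raster.copy(deep=True)
        ds["emt"] = ds["emt"] + off
        ds["map"] = ds["map"] * fac
        ds["sst"] = ds["sst"] + slope * off
        ds.attrs = dict(raster.attrs)
        ds.attrs["scenario"] = s
        out[s] = ds
    return out


def apply_scenario_to_points(table: pd.DataFrame, emt_offset: float, map_factor: float = 1.0) -> pd.DataFrame:
    """Point-level analog of :func:`make_future_climate`."""
    out = table.copy()
    out["EMT"] = out["EMT"] + float(emt_offset)
    out["MAP"] = out["MAP"] * float(map_factor)
    return out


# --------------------------------------------------------------------------
# HURDAT2 tracks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackParams:
    """Parameters for one synthetic storm track (six-hourly fixes)."""

    name: str
    year: int
    number: int
    t0: np.datetime64
    lon0: float
    lat0: float
    n_fixes: int
    heading_deg: float = 20.0       # mean direction of motion, clockwise from N
    heading_jitter: float = 0.0     # uniform +/- jitter per segment
    speed_kmh: float = 25.0
    wind_kt_range: tuple = (40, 90)
    basin: str = "AL"

    def __post_init__(self):
        if self.n_fixes < 2:
            raise ValueError("a track needs at least 2 fixes for a segment direction")


def _destination(lon, lat, bearing_deg, dist_km):
    """Great-circle destination point (spherical Earth)."""
    R = EARTH_RADIUS_M / 1000.0
    delta = dist_km / R
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return float(np.degrees(lam2)), float(np.degrees(phi2))


def make_synthetic_hurdat2(tracks_params, seed: int) -> str:
    """HURDAT2 v2-dialect text for the given synthetic storms."""
    params = list(tracks_params)
    if len(params) < 1:
        raise ValueError("at least one track is required")
    rng = substream(seed, "hurdat2")
    tracks = []
    for tp in params:
        lon, lat = float(tp.lon0), float(tp.lat0)
        wind = int(rng.integers(tp.wind_kt_range[0], tp.wind_kt_range[1] + 1))
        fixes = []
        t = np.datetime64(tp.t0)
        for _ in range(tp.n_fixes):
            status = "HU" if wind >= 64 else ("TS" if wind >= 34 else "TD")
            fixes.append(
                Fix(
                    time=t,
                    record_id="",
                    status=status,
                    lat=round(lat, 1),
                    lon=round(lon, 1),
                    wind_kt=wind,
                    pressure_mb=int(1010 - wind),
                )
            )
            heading = tp.heading_deg + (
                rng.uniform(-tp.heading_jitter, tp.heading_jitter) if tp.heading_jitter > 0 else 0.0
            )
            lon, lat = _destination(lon, lat, heading, tp.speed_kmh * 6.0)
            wind = int(np.clip(wind + rng.integers(-5, 6), tp.wind_kt_range[0], tp.wind_kt_range[1]))
            t = t + np.timedelta64(6, "h")
        tracks.append(StormTrack(basin=tp.basin, number=tp.number, year=tp.year, name=tp.name, fixes=fixes))
    return serialize_hurdat2(tracks)
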