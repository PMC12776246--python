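"""Lagrangian surface-drift simulation of buoyant propagules.

Particles are released hourly from coastal source cells and advected through
hourly surface-velocity snapshots with a first-order Euler scheme, bilinear
in space and linear in time between snapshots.  A particle terminates in
exactly one of three states:

``stranded``
    first arrival in a coastal ocean cell (an ocean cell with a land
    8-neighbour) *after* its minimum floating period has elapsed;
``expired``
    the maximum floating period passed without stranding;
``out_of_domain``
    the particle left the model domain.

The minimum floating period is drawn per particle from a continuous
Uniform[1, 5] days, which suppresses immediate re-stranding at the release
site and lets long-distance dispersal events develop.  Vertical motion,
windage and diffusion are all neglected: propagules are treated as passive
surface floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import (
    METERS_PER_DEGREE,
    DomainSpec,
    GridMask,
    coastal_cells,
    great_circle_km,
    substream,
)

#: Days per month used to convert "months afloat" into steps, calendar-free.
DAYS_PER_MONTH = 30.44

#: Maximum floating periods (months) reported for the study species.
ALLOWED_MAX_FLOATS = (1, 3, 6, 12, 17)

STATUS_STRANDED = "stranded"
STATUS_EXPIRED = "expired"
STATUS_OUT_OF_DOMAIN = "out_of_domain"


class CoverageError(ValueError):
    """A query or schedule fell outside the velocity field's coverage."""


@dataclass
class VelocityField:
    """Hourly u,v (m/s) on the node lattice of a regular lat-lon grid.

    ``u`` and ``v`` have shape ``[n_hours, n_lat + 1, n_lon + 1]`` — values
    sit on cell corners.  ``node_valid`` marks nodes that touch at least one
    ocean cell; velocities at invalid (fully land-locked) nodes are never
    interpolated into ocean queries.
    """

    spec: DomainSpec
    u: np.ndarray
    v: np.ndarray
    node_valid: np.ndarray | None = None

    def __post_init__(self):
        shape = (self.spec.n_hours, self.spec.n_lat + 1, self.spec.n_lon + 1)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")
        if self.node_valid is None:
            self.node_valid = np.ones(shape[1:], dtype=bool)
        if not (np.isfinite(self.u[:, self.node_valid]).all() and np.isfinite(self.v[:, self.node_valid]).all()):
            raise ValueError("non-finite velocities on valid nodes")

    @property
    def times(self) -> np.ndarray:
        return self.spec.times

    def hours_since_t0(self, t) -> float:
        return float((np.datetime64(t) - self.spec.t0) / np.timedelta64(1, "h"))


def mask_field_nodes(field: VelocityField, mask: GridMask) -> VelocityField:
    """Invalidate nodes surrounded entirely by land cells."""
    land = mask.land
    padded = np.pad(land, 1, mode="constant", constant_values=True)
    # node (i, j) touches cells (i-1..i, j-1..j) => padded window (i:i+2, j:j+2)
    valid = np.zeros((land.shape[0] + 1, land.shape[1] + 1), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            valid |= ~padded[di : di + valid.shape[0], dj : dj + valid.shape[1]]
    return VelocityField(field.spec, field.u, field.v, node_valid=valid)


def _spatial_interp(snap: np.ndarray, valid: np.ndarray, row, col, fx, fy):
    """Bilinear interpolation with nearest-valid-corner fallback.

    ``snap`` is one [lat, lon] node snapshot; invalid corners take the value
    of the nearest valid corner of the same cell before the bilinear blend.
    """
    c00 = snap[row, col]
    c01 = snap[row, col + 1]
    c10 = snap[row + 1, col]
    c11 = snap[row + 1, col + 1]
    v00 = valid[row, col]
    v01 = valid[row, col + 1]
    v10 = valid[row + 1, col]
    v11 = valid[row + 1, col + 1]
    any_invalid = ~(v00 & v01 & v10 & v11)
    if np.any(any_invalid):
        big = np.inf
        d = np.stack(
            [
                np.where(v00, fx**2 + fy**2, big),
                np.where(v01, (1 - fx) ** 2 + fy**2, big),
                np.where(v10, fx**2 + (1 - fy) ** 2, big),
                np.where(v11, (1 - fx) ** 2 + (1 - fy) ** 2, big),
            ]
        )
        if np.any(np.isinf(d.min(axis=0))):
            raise CoverageError("velocity query in a cell with no valid node")
        nearest = np.take_along_axis(
            np.stack([c00, c01, c10, c11]), d.argmin(axis=0)[None], axis=0
        )[0]
        c00 = np.where(v00, c00, nearest)
        c01 = np.where(v01, c01, nearest)
        c10 = np.where(v10, c10, nearest)
        c11 = np.where(v11, c11, nearest)
    return (
        c00 * (1 - fx) * (1 - fy)
        + c01 * fx * (1 - fy)
        + c10 * (1 - fx) * fy
        + c11 * fx * fy
    )


def interp_velocity(field: VelocityField, lon, lat, t):
    """Velocity (u, v) in m/s at points and time ``t``.

    ``t`` is either a timestamp or float hours since the field's first
    snapshot; space is bilinear between the four surrounding nodes, time is
    linear between the two bracketing hourly snapshots.
    """
    spec = field.spec
    scalar = np.isscalar(lon) and np.isscalar(lat)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    th = t if isinstance(t, (int, float, np.floating)) else field.hours_since_t0(t)
    th = float(th)
    if th < 0 or th > spec.n_hours - 1:
        raise CoverageError(f"time {th} h outside field coverage [0, {spec.n_hours - 1}] h")
    if np.any(~spec.contains(lon, lat)):
        raise CoverageError("query point outside the spatial domain")

    row, col = spec.cell_index(lon, lat)
    fx = (lon - (spec.lon_min + col * spec.resolution)) / spec.resolution
    fy = (lat - (spec.lat_min + row * spec.resolution)) / spec.resolution

    k = min(int(np.floor(th)), spec.n_hours - 2) if spec.n_hours > 1 else 0
    ft = th - k
    out = []
    for comp in (field.u, field.v):
        a = _spatial_interp(comp[k], field.node_valid, row, col, fx, fy)
        if ft > 0 and spec.n_hours > 1:
            b = _spatial_interp(comp[k + 1], field.node_valid, row, col, fx, fy)
            a = (1 - ft) * a + ft * b
        out.append(a)
    u, v = out
    return (float(u[0]), float(v[0])) if scalar else (u, v)


def euler_step(lon, lat, u, v, dt):
    """One forward-Euler step of ``dt`` seconds on the sphere.

    Velocities in m/s are converted to angular displacements with the
    suite-wide Earth constant; the longitude conversion carries the
    1/cos(lat) metric factor, guarded away from the poles.
    """
    lat_arr = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat_arr) >= 89.0):
        raise ValueError("advection restricted to |lat| < 89 degrees")
    if dt <= 0:
        raise ValueError("dt must be positive")
    dlat = np.asarray(v, dtype=float) * dt / METERS_PER_DEGREE
    dlon = np.asarray(u, dtype=float) * dt / (METERS_PER_DEGREE * np.cos(np.radians(lat_arr)))
    return np.asarray(lon, dtype=float) + dlon, lat_arr + dlat


@dataclass
class ReleaseSchedule:
    """Hourly release events: unique source cells x hourly times in a window."""

    spec: DomainSpec
    cells: np.ndarray  # (n_cells, 2) int (row, col)
    start: np.datetime64
    end: np.datetime64  # half-open [start, end)

    @property
    def release_times(self) -> np.ndarray:
        n = int((np.datetime64(self.end) - np.datetime64(self.start)) / np.timedelta64(1, "h"))
        if n < 1:
            raise ValueError("release window shorter than one hour")
        return np.datetime64(self.start) + np.arange(n).astype("timedelta64[h]")

    @property
    def n_events(self) -> int:
        return len(self.cells) * len(self.release_times)

    def events(self):
        """(row, col, time) per release event, cell-major."""
        times = self.release_times
        rows = np.repeat(self.cells[:, 0], len(times))
        cols = np.repeat(self.cells[:, 1], len(times))
        tt = np.tile(times, len(self.cells))
        return rows, cols, tt


def build_release_schedule(mask: GridMask, source_points, window, waterbody_config=None) -> ReleaseSchedule:
    """Resolve source points to ocean release cells.

    Points inside a lagoon are reassigned to their waterbody's inlet cell
    (propagules behind a dispersal barrier enter the ocean at the inlet);
    points on land or off-grid snap to the nearest coastal ocean cell by
    great-circle distance; duplicate cells are removed, preserving first
    appearance.
    """
    spec = mask.spec
    pts = np.asarray(source_points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("at least one source point is required")
    coast = np.argwhere(mask.coastal)
    if len(coast) == 0:
        raise ValueError("mask has no coastal cells")
    coast_lon = spec.lon_centers[coast[:, 1]]
    coast_lat = spec.lat_centers[coast[:, 0]]

    inlet_cells = {}
    for wid, (ilon, ilat) in mask.waterbodies.items():
        r, c = spec.cell_index(ilon, ilat)
        inlet_cells[wid] = (int(r), int(c))
    if waterbody_config is not None:
        for wid, (ilon, ilat) in waterbody_config.inlets.items():
            r, c = spec.cell_index(ilon, ilat)
            inlet_cells[wid] = (int(r), int(c))

    chosen = []
    for lon, lat in pts:
        row, col = spec.cell_index(lon, lat)
        row, col = int(row), int(col)
        if row >= 0 and col >= 0 and mask.lagoon_id[row, col] > 0:
            wid = f"lagoon_{int(mask.lagoon_id[row, col])}"
            if wid not in inlet_cells:
                raise ValueError(f"no inlet configured for waterbody {wid}")
            chosen.append(inlet_cells[wid])
            continue
        if row >= 0 and col >= 0 and mask.coastal[row, col]:
            chosen.append((row, col))
            continue
        d = great_circle_km(lon, lat, coast_lon, coast_lat)
        ties = np.where(d == d.min())[0]  # ties broken by lowest (lat, lon) index
        k = int(ties[np.lexsort((coast[ties, 1], coast[ties, 0]))[0]])
        chosen.append((int(coast[k, 0]), int(coast[k, 1])))

    seen, cells = set(), []
    for rc in chosen:
        if rc not in seen:
            seen.add(rc)
            cells.append(rc)
    start, end = np.datetime64(window[0]), np.datetime64(window[1])
    t_last = spec.t0 + np.timedelta64(spec.n_hours - 1, "h")
    if start < spec.t0 or end > t_last + np.timedelta64(1, "h"):
        raise CoverageError("release window extends past field coverage")
    return ReleaseSchedule(spec, np.array(cells, dtype=int), start, end)


@dataclass
class Trajectory:
    """One particle's release, hourly path and terminal state."""

    particle_id: int
    release_cell: tuple
    release_time: np.datetime64
    min_float_days: float
    status: str
    times: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    stranding_cell: tuple | None = None
    stranding_time: np.datetime64 | None = None

    @property
    def stranding_lonlat(self):
        if self.stranding_cell is None:
            return None
        return (float(self.lons[-1]), float(self.lats[-1]))


def advect(
    field: VelocityField,
    mask: GridMask,
    schedule: ReleaseSchedule,
    max_float_months: float,
    min_float_range=(1.0, 5.0),
    seed: int = 0,
) -> list[Trajectory]:
    """Advect every scheduled particle to termination.

    Hourly Euler steps; a step that would land on a land cell holds the
    particle in place for that hour (shear past the coast resumes next
    step); stranding fires at the first hour the particle occupies a coastal
    ocean cell with its minimum floating period elapsed.
    """
    spec = field.spec
    max_steps = int(round(max_float_months * DAYS_PER_MONTH * 24))
    rows0, cols0, rel_times = schedule.events()
    n = len(rows0)
    rel_idx = ((rel_times - spec.t0) / np.timedelta64(1, "h")).astype(float)
    if np.any(rel_idx != np.round(rel_idx)):
        raise ValueError("release times must fall on the hourly grid")
    rel_idx = rel_idx.astype(int)
    horizon = int(rel_idx.max()) + max_steps
    if horizon > spec.n_hours - 1:
        raise CoverageError(
            f"schedule + max float needs {horizon + 1} hourly snapshots, field has {spec.n_hours}"
        )

    rng = substream(seed, "tracker.min_float")
    lo, hi = min_float_range
    min_float_days = rng.uniform(lo, hi, size=n)
    min_float_h = min_float_days * 24.0

    lon = spec.lon_centers[cols0].astype(float).copy()
    lat = spec.lat_centers[rows0].astype(float).copy()
    status = np.full(n, "", dtype=object)
    end_idx = np.full(n, -1, dtype=int)
    strand_rc = np.full((n, 2), -1, dtype=int)
    coastal = mask.coastal

    t_first = int(rel_idx.min())
    pos = np.full((horizon - t_first + 2, n, 2), np.nan, dtype=np.float64)
    pos[rel_idx - t_first, np.arange(n), 0] = lon
    pos[rel_idx - t_first, np.arange(n), 1] = lat
    alive = np.zeros(n, dtype=bool)

    for k in range(t_first, horizon + 1):
        alive |= rel_idx == k
        act = alive.copy()
        if not act.any():
            continue
        u, v = interp_velocity(field, lon[act], lat[act], float(k))
        nlon, nlat = euler_step(lon[act], lat[act], u, v, 3600.0)
        inside = spec.contains(nlon, nlat)
        rowc = np.full(inside.shape, -1, dtype=int)
        colc = np.full(inside.shape, -1, dtype=int)
        rowc[inside], colc[inside] = spec.cell_index(nlon[inside], nlat[inside])
        hits_land = np.zeros_like(inside)
        hits_land[inside] = mask.land[rowc[inside], colc[inside]]
        # hold at previous position where the step would beach the particle
        move = inside & ~hits_land
        idx = np.where(act)[0]
        lon[idx[move]] = nlon[move]
        lat[idx[move]] = nlat[move]
        # leaving the domain terminates the particle at its last position
        left = idx[~inside]
        status[left] = STATUS_OUT_OF_DOMAIN
        end_idx[left] = k
        alive[left] = False

        still = idx[inside]
        pos[k + 1 - t_first, still, 0] = lon[still]
        pos[k + 1 - t_first, still, 1] = lat[still]
        elapsed = (k + 1) - rel_idx[still]
        r2, c2 = spec.cell_index(lon[still], lat[still])
        is_coastal = coastal[r2, c2]
        strand = is_coastal & (elapsed >= min_float_h[still])
        sids = still[strand]
        status[sids] = STATUS_STRANDED
        end_idx[sids] = k + 1
        strand_rc[sids, 0] = r2[strand]
        strand_rc[sids, 1] = c2[strand]
        alive[sids] = False

        expire = still[~strand][(elapsed[~strand]) >= max_steps]
        status[expire] = STATUS_EXPIRED
        end_idx[expire] = k + 1
        alive[expire] = False

    if alive.any():  # pragma: no cover - coverage precondition prevents this
        raise RuntimeError("particles still active at end of field coverage")

    trajectories = []
    for i in range(n):
        k0, k1 = rel_idx[i] - t_first, end_idx[i] - t_first
        lons = pos[k0 : k1 + 1, i, 0]
        lats = pos[k0 : k1 + 1, i, 1]
        keep = ~np.isnan(lons)
        steps = np.arange(k0, k1 + 1)[keep]
        tt = spec.t0 + ((steps + t_first).astype("timedelta64[h]"))
        tr = Trajectory(
            particle_id=i,
            release_cell=(int(rows0[i]), int(cols0[i])),
            release_time=rel_times[i],
            min_float_days=float(min_float_days[i]),
            status=str(status[i]),
            times=tt,
            lons=lons[keep].copy(),
            lats=lats[keep].copy(),
        )
        if tr.status == STATUS_STRANDED:
            tr.stranding_cell = (int(strand_rc[i, 0]), int(strand_rc[i, 1]))
            tr.stranding_time = spec.t0 + np.timedelta64(int(end_idx[i]), "h")
        trajectories.append(tr)
    return trajectories


def trajectory_density(trajectories, spec: DomainSpec) -> np.ndarray:
    """Count of distinct trajectories intersecting each grid cell.

    A trajectory contributes at most one count per cell no matter how many
    hourly positions fall inside it.
    """
    dens = np.zeros((spec.n_lat, spec.n_lon), dtype=np.int64)
    for tr in trajectories:
        row, col = spec.cell_index(tr.lons, tr.lats)
        ok = (row >= 0) & (col >= 0)
        cells = np.unique(row[ok] * spec.n_lon + col[ok])
        dens[cells // spec.n_lon, cells % spec.n_lon] += 1
    return dens


def summarize_trajectories(trajectories, spec: DomainSpec) -> pd.DataFrame:
    """Per-particle summary table (release, min float, status, stranding)."""
    rows = []
    for tr in trajectories:
        stranding = tr.stranding_lonlat
        rows.append(
            {
                "particle_id": tr.particle_id,
                "release_row": tr.release_cell[0],
                "release_col": tr.release_cell[1],
                "release_lon": float(spec.lon_centers[tr.release_cell[1]]),
                "release_lat": float(spec.lat_centers[tr.release_cell[0]]),
                "release_time": pd.Timestamp(tr.release_time),
                "min_float_days": tr.min_float_days,
                "status": tr.status,
                "stranding_lon": stranding[0] if stranding else np.nan,
                "stranding_lat": stranding[1] if stranding else np.nan,
                "stranding_time": pd.Timestamp(tr.stranding_time) if tr.stranding_time is not None else pd.NaT,
            }
        )
    return pd.DataFrame(rows)
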