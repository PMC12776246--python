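"""Shared geometry, grid and RNG primitives.

Everything in the suite lives on a spherical Earth of radius 6371 km and on
regular latitude-longitude grids whose cells are half-open
``[edge, edge + resolution)`` in both axes.  Field values used for
interpolation sit on the cell *corners* (nodes), so a grid with ``n`` cells
along an axis carries ``n + 1`` nodes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

#: Spherical Earth radius, metres. One constant for the whole suite so the
#: analytic advection oracles stay closed-form.
EARTH_RADIUS_M = 6_371_000.0

#: Metres per degree of arc on that sphere (also metres per degree of
#: longitude at the equator).
METERS_PER_DEGREE = np.pi * EARTH_RADIUS_M / 180.0

# Habitat classes carried by coastal ocean cells.
HABITAT_NONE = 0
HABITAT_MANGROVE = 1
HABITAT_SALTMARSH = 2
HABITAT_INLET = 3
HABITAT_URBAN = 4
HABITAT_OTHER = 5

HABITAT_NAMES = {
    HABITAT_NONE: "none",
    HABITAT_MANGROVE: "mangrove",
    HABITAT_SALTMARSH: "saltmarsh",
    HABITAT_INLET: "inlet",
    HABITAT_URBAN: "urban",
    HABITAT_OTHER: "other",
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream fanned out from one integer seed.

    Every stochastic component draws from its own named stream so modules
    stay independent: adding draws in one stage never shifts another.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (broadcasts)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class DomainSpec:
    """Regular lat-lon model domain with an hourly clock.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Domain bounds in degrees; cells tile ``[min, max)``.
    resolution
        Cell size in degrees (default 1/24, the native ocean-model grid).
    t0
        Timestamp of the first hourly snapshot.
    n_hours
        Number of hourly steps covered by time-dependent fields.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 1.0 / 24.0
    t0: np.datetime64 = field(default=np.datetime64("2011-08-01T00:00"))
    n_hours: int = 24

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("domain bounds must satisfy min < max on both axes")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")
        if not (-180.0 <= self.lon_min and self.lon_max <= 180.0):
            raise ValueError("longitudes must lie in [-180, 180]")
        if not (-90.0 <= self.lat_min and self.lat_max <= 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution * np.arange(self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.resolution * np.arange(self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_edges[:-1] + self.resolution / 2.0

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_edges[:-1] + self.resolution / 2.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_hours).astype("timedelta64[h]")

    def cell_index(self, lon, lat):
        """Map points to (row, col) cell indices under the half-open rule.

        Out-of-domain points get index -1 on the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        col = np.where((lon >= self.lon_min) & (lon < self.lon_max), col, -1)
        row = np.where((lat >= self.lat_min) & (lat < self.lat_max), row, -1)
        return row, col

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )


@dataclass
class GridMask:
    """Land/ocean classification with coastal habitat classes.

    ``land`` is a boolean cell array ``[lat, lon]``; ``habitat`` carries a
    habitat code on coastal ocean cells (0 elsewhere); ``lagoon_id`` is 0 for
    open water/land and ``k >= 1`` for cells inside lagoon ``k``.
    ``waterbodies`` maps ``"lagoon_<k>"`` to the (lon, lat) of its inlet cell
    centre.
    """

    spec: DomainSpec
    land: np.ndarray
    habitat: np.ndarray
    lagoon_id: np.ndarray
    waterbodies: dict

    def __post_init__(self):
        shape = (self.spec.n_lat, self.spec.n_lon)
        for name in ("land", "habitat", "lagoon_id"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.land.all() or (~self.land).all():
            raise ValueError("degenerate domain: mask is all land or all ocean")

    @property
    def ocean(self) -> np.ndarray:
        return ~self.land

    @property
    def coastal(self) -> np.ndarray:
        """Ocean cells with at least one land 8-neighbour."""
        return coastal_cells(self.land)

    def is_land(self, lon, lat):
        row, col = self.spec.cell_index(lon, lat)
        ok = (row >= 0) & (col >= 0)
        out = np.zeros(np.shape(ok), dtype=bool)
        out[ok] = self.land[row[ok], col[ok]]
        return out


def coastal_cells(land: np.ndarray) -> np.ndarray:
    """Ocean cells adjacent (8-connected) to at least one land cell."""
    padded = np.pad(land, 1, mode="constant", constant_values=False)
    neigh = np.zeros_like(land, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh |= padded[1 + di : 1 + di + land.shape[0], 1 + dj : 1 + dj + land.shape[1]]
    return (~land) & neigh


def flood_fill_ocean(land: np.ndarray, seeds) -> np.ndarray:
    """4-connected flood fill over ocean cells from seed (row, col) pairs.

    Water connectivity is deliberately 4-connected so that two ocean cells
    touching only at a corner (across a land diagonal) do not leak.
    """
    from collections import deque

    reached = np.zeros_like(land, dtype=bool)
    q = deque()
    for r, c in seeds:
        if 0 <= r < land.shape[0] and 0 <= c < land.shape[1] and not land[r, c]:
            if not reached[r, c]:
                reached[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < land.shape[0] and 0 <= cc < land.shape[1]:
                if not land[rr, cc] and not reached[rr, cc]:
                    reached[rr, cc] = True
                    q.append((rr, cc))
    return reached
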