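"""Storm-track statistics: HURDAT2 parsing, path directions, wind roses.

Tracks come as six-hourly best-track fixes.  For each consecutive pair of
fixes we compute the initial great-circle bearing (degrees clockwise from
true north) and reverse it by 180 deg, yielding the meteorological
"direction from which the storm travels"; those directions, stratified by
Saffir-Simpson intensity class of the originating fix, are binned into
16-sector wind-rose tables for the propagule-release season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

KT_TO_KMH = 1.852

#: Saffir-Simpson class lower bounds in km/h as conventionally printed.
SS_KMH_BOUNDS = ((5, 252.0), (4, 209.0), (3, 178.0), (2, 154.0), (1, 119.0))

#: The scale as defined, in knots.
SS_KT_BOUNDS = ((5, 137), (4, 113), (3, 96), (2, 83), (1, 64))

#: 16-point compass labels, clockwise from north.
COMPASS_16 = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)

#: Propagule-presence season (peak release months).
DEFAULT_SEASON_MONTHS = (8, 9, 10)

#: Default east-coast-of-Florida retention box (lon_min, lat_min, lon_max, lat_max).
DEFAULT_REGION_BOX = (-82.0, 24.0, -79.0, 31.0)


class Hurdat2ParseError(ValueError):
    def __init__(self, message, line_no=None):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}" if line_no else message)


@dataclass(frozen=True)
class Fix:
    """One best-track fix: time, position, intensity."""

    time: np.datetime64
    record_id: str
    status: str
    lat: float
    lon: float
    wind_kt: int
    pressure_mb: int


@dataclass
class StormTrack:
    basin: str
    number: int
    year: int
    name: str
    fixes: list

    @property
    def storm_id(self) -> str:
        return f"{self.basin}{self.number:02d}{self.year:04d}"


@dataclass(frozen=True)
class PathSegment:
    """Directed segment between consecutive fixes of one track."""

    storm_id: str
    from_time: np.datetime64
    bearing: float          # initial great-circle bearing of motion, deg from N
    direction_from: float   # bearing reversed by 180 deg, in [0, 360)
    wind_kt: int
    category: str           # Saffir-Simpson class or "TD/TS"
    month: int


# --------------------------------------------------------------------------
# HURDAT2 text
# --------------------------------------------------------------------------

def parse_hurdat2(text: str):
    """Parse HURDAT2 second-generation text into storm tracks.

    Tolerant of variable padding; a malformed track raises a per-track
    error carrying the offending line number while other tracks parse.
    Returns ``(tracks, errors)``.
    """
    tracks, errors = [], []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        header = [f.strip() for f in lines[i].split(",")]
        line_no = i + 1
        try:
            storm_id, name, count = header[0], header[1], int(header[2])
            basin, number, year = storm_id[:2], int(storm_id[2:4]), int(storm_id[4:8])
        except (IndexError, ValueError):
            raise Hurdat2ParseError(f"malformed header: {lines[i]!r}", line_no)
        fix_lines = lines[i + 1 : i + 1 + count]
        i += 1 + count
        if len(fix_lines) != count:
            errors.append(Hurdat2ParseError(f"header announces {count} fixes, file has {len(fix_lines)}", line_no))
            continue
        try:
            fixes = [_parse_fix(ln, line_no + 1 + j) for j, ln in enumerate(fix_lines)]
            times = [f.time for f in fixes]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise Hurdat2ParseError("fix times not strictly increasing", line_no)
            tracks.append(StormTrack(basin=basin, number=number, year=year, name=name, fixes=fixes))
        except Hurdat2ParseError as exc:
            errors.append(exc)
    return tracks, errors


def _parse_fix(line: str, line_no: int) -> Fix:
    f = [x.strip() for x in line.split(",")]
    try:
        t = np.datetime64(f"{f[0][:4]}-{f[0][4:6]}-{f[0][6:8]}T{f[1][:2]}:{f[1][2:4]}")
        lat_tok, lon_tok = f[4], f[5]
        lat = float(lat_tok[:-1]) * (1 if lat_tok[-1] == "N" else -1)
        lon = float(lon_tok[:-1]) * (1 if lon_tok[-1] == "E" else -1)
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError("coordinate out of range")
        wind = int(f[6])
        if wind < 0:
            raise ValueError("negative wind")
        return Fix(time=t, record_id=f[2], status=f[3], lat=lat, lon=lon, wind_kt=wind, pressure_mb=int(f[7]))
    except (IndexError, ValueError) as exc:
        raise Hurdat2ParseError(f"malformed fix {line!r}: {exc}", line_no) from None


def serialize_hurdat2(tracks) -> str:
    """Canonical HURDAT2 text (fixed-width padding, trailing commas)."""
    out = []
    for tr in tracks:
        out.append(f"{tr.storm_id},{tr.name:>19},{len(tr.fixes):>7},")
        for fx in tr.fixes:
            ts = pd.Timestamp(fx.time)
            lat_h = "N" if fx.lat >= 0 else "S"
            lon_h = "E" if fx.lon >= 0 else "W"
            out.append(
                f"{ts:%Y%m%d}, {ts:%H%M},{fx.record_id:>2}, {fx.status:>2},"
                f" {abs(fx.lat):4.1f}{lat_h}, {abs(fx.lon):5.1f}{lon_h},"
                f" {fx.wind_kt:3d}, {fx.pressure_mb:4d},"
            )
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# directions and intensity
# --------------------------------------------------------------------------

def initial_bearing(lon1, lat1, lon2, lat2) -> float:
    """Initial great-circle bearing from point 1 to point 2, deg from north."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def saffir_simpson(wind_kmh: float) -> str:
    """Saffir-Simpson class from sustained wind in km/h (printed bounds).

    Category 1 spans [119, 154) km/h, Category 2 [154, 178), Category 3
    [178, 209), Category 4 [209, 252), Category 5 >= 252; anything below
    hurricane force is pooled as "TD/TS".
    """
    w = float(wind_kmh)
    if w < 0:
        raise ValueError("wind speed must be non-negative")
    for cat, lo in SS_KMH_BOUNDS:
        if w >= lo:
            return str(cat)
    return "TD/TS"


def saffir_simpson_from_knots(wind_kt: float) -> str:
    """Saffir-Simpson class from wind in knots (the scale's defining unit)."""
    w = float(wind_kt)
    if w < 0:
        raise ValueError("wind speed must be non-negative")
    for cat, lo in SS_KT_BOUNDS:
        if w >= lo:
            return str(cat)
    return "TD/TS"


def segment_directions(track: StormTrack):
    """Per-segment path directions with intensity class of the from-fix.

    Direction is the initial bearing of motion reversed by 180 deg (the
    direction the storm comes *from*).  Coincident consecutive fixes yield
    no segment; the skipped pairs are returned alongside.
    """
    if len(track.fixes) < 2:
        raise ValueError("segment directions need at least 2 fixes")
    segments, skipped = [], []
    for a, b in zip(track.fixes, track.fixes[1:]):
        if a.lat == b.lat and a.lon == b.lon:
            skipped.append((a.time, b.time))
            continue
        brg = initial_bearing(a.lon, a.lat, b.lon, b.lat)
        segments.append(
            PathSegment(
                storm_id=track.storm_id,
                from_time=a.time,
                bearing=brg,
                direction_from=(brg + 180.0) % 360.0,
                wind_kt=a.wind_kt,
                category=saffir_simpson_from_knots(a.wind_kt),
                month=int(pd.Timestamp(a.time).month),
            )
        )
    return segments, skipped


def region_polygon_from_box(box=DEFAULT_REGION_BOX) -> Polygon:
    lon0, lat0, lon1, lat1 = box
    return Polygon([(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)])


def filter_tracks(tracks, region_polygon: Polygon, months=DEFAULT_SEASON_MONTHS, years=None):
    """Retain tracks with >= 1 fix inside the region; filter segments by month.

    Returns ``(retained_tracks, segments)`` where segments come only from
    retained tracks and only where the from-fix month is in ``months``
    (and, when given, the year within the inclusive ``years`` range).
    """
    if region_polygon.is_empty:
        raise ValueError("empty region polygon")
    months = set(int(m) for m in months)
    if not months <= set(range(1, 13)):
        raise ValueError("months must be within 1..12")
    retained, segments = [], []
    for tr in tracks:
        if years is not None and not (years[0] <= tr.year <= years[1]):
            continue
        if not any(region_polygon.covers(Point(fx.lon, fx.lat)) for fx in tr.fixes):
            continue
        retained.append(tr)
        if len(tr.fixes) < 2:
            continue
        segs, _ = segment_directions(tr)
        segments.extend(s for s in segs if s.month in months)
    return retained, segments


# --------------------------------------------------------------------------
# wind roses
# --------------------------------------------------------------------------

def sector_index(direction_deg: float, n_sectors: int = 16) -> int:
    """Sector of a direction; sector 0 is centred on north, half-open on the
    clockwise edge: with 16 sectors, [348.75, 11.25) -> N, [11.25, 33.75) -> NNE."""
    width = 360.0 / n_sectors
    return int(((direction_deg + width / 2.0) % 360.0) // width)


def sector_labels(n_sectors: int):
    if n_sectors == 16:
        return list(COMPASS_16)
    width = 360.0 / n_sectors
    return [f"{(i * width) % 360:g}deg" for i in range(n_sectors)]


def windrose_table(segments, n_sectors: int = 16) -> pd.DataFrame:
    """Long-form wind-rose table: sector x intensity class counts/frequencies.

    Frequencies normalise by the total segment count, so they sum to 1 on a
    non-empty table.  An empty segment list yields an empty (flagged) table.
    """
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")
    labels = sector_labels(n_sectors)
    cats = ["TD/TS", "1", "2", "3", "4", "5"]
    counts = np.zeros((n_sectors, len(cats)), dtype=int)
    for seg in segments:
        counts[sector_index(seg.direction_from, n_sectors), cats.index(seg.category)] += 1
    total = counts.sum()
    rows = []
    for i, lab in enumerate(labels):
        for j, cat in enumerate(cats):
            rows.append(
                {
                    "sector": lab,
                    "sector_center_deg": (i * 360.0 / n_sectors) % 360.0,
                    "category": cat,
                    "count": int(counts[i, j]),
                    "frequency": counts[i, j] / total if total else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["empty"] = bool(total == 0)
    return table


def monthly_windrose_tables(segments, n_sectors: int = 16) -> dict:
    """One wind-rose table per calendar month present in the segments."""
    out = {}
    for month in sorted({s.month for s in segments}):
        out[month] = windrose_table([s for s in segments if s.month == month], n_sectors)
    return out
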