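"""Covariate preparation for the occurrence table.

Two concerns live here: (i) completing missing climate values — records
inside enclosed waterbodies take the SST of their waterbody's inlet, all
other gaps take the nearest non-missing raster cell by great-circle
distance — and (ii) collinearity screening of the candidate predictors with
Spearman rank correlation, dropping the lower-priority member of any pair
with |rho| above the threshold (SST is routinely the casualty, being nearly
a monotone transform of extreme minimum temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .domain import great_circle_km

#: Column names of the candidate predictors, in default priority order.
DEFAULT_PRIORITY = ("EMT", "MAP", "SST")

#: |Spearman rho| above which a predictor pair counts as collinear.
DEFAULT_RHO_THRESHOLD = 0.5

RASTER_VAR_FOR_COLUMN = {"EMT": "emt", "MAP": "map", "SST": "sst"}


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length 1-d sequences of length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs must not contain missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("rank correlation undefined for a constant input")
    return float(stats.spearmanr(x, y).statistic)


def screen_predictors(table: pd.DataFrame, candidates=DEFAULT_PRIORITY, threshold=DEFAULT_RHO_THRESHOLD):
    """Drop lower-priority predictors from collinear pairs.

    Walks the candidates in priority order, retaining one only if its
    |rho| with every already-retained predictor stays at or below the
    threshold; applied transitively this keeps exactly the top-priority
    member of any mutually collinear group.

    Returns ``(retained, report)`` where the report lists every pairwise
    rho and whether the pair triggered a drop.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    for c in candidates:
        if c not in table.columns:
            raise ValueError(f"candidate {c!r} not in table")

    pairs = []
    rho_of = {}
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            rho = spearman_rho(table[a].to_numpy(), table[b].to_numpy())
            rho_of[(a, b)] = rho_of[(b, a)] = rho
            pairs.append({"a": a, "b": b, "rho": rho, "collinear": abs(rho) > threshold})

    retained, dropped = [], []
    for c in candidates:
        clash = [r for r in retained if abs(rho_of[(c, r)]) > threshold]
        if clash:
            dropped.append({"predictor": c, "collinear_with": clash[0], "rho": rho_of[(c, clash[0])]})
        else:
            retained.append(c)
    report = pd.DataFrame(pairs)
    report.attrs["dropped"] = dropped
    return retained, report


@dataclass
class WaterbodyConfig:
    """Maps each waterbody id to the (lon, lat) of its ocean inlet."""

    inlets: dict = field(default_factory=dict)

    @classmethod
    def from_mask(cls, mask) -> "WaterbodyConfig":
        return cls(inlets=dict(mask.waterbodies))

    @classmethod
    def from_csv(cls, path) -> "WaterbodyConfig":
        df = pd.read_csv(path)
        return cls(inlets={str(r.waterbody_id): (float(r.inlet_lon), float(r.inlet_lat)) for r in df.itertuples()})

    def to_csv(self, path):
        pd.DataFrame(
            [{"waterbody_id": k, "inlet_lon": v[0], "inlet_lat": v[1]} for k, v in self.inlets.items()]
        ).to_csv(path, index=False)


def _nearest_cell_value(da: xr.DataArray, lon: float, lat: float):
    """Value of the nearest non-missing cell by great-circle distance.

    Distance ties break toward the lowest (lat, lon) cell index for
    determinism.
    """
    vals = da.values
    ok = np.argwhere(~np.isnan(vals))
    if len(ok) == 0:
        raise ValueError(f"raster {da.name!r} entirely missing over the domain")
    cell_lat = da["lat"].values[ok[:, 0]]
    cell_lon = da["lon"].values[ok[:, 1]]
    d = great_circle_km(lon, lat, cell_lon, cell_lat)
    ties = np.where(d == d.min())[0]
    k = int(ties[np.lexsort((ok[ties, 1], ok[ties, 0]))[0]])
    return float(vals[ok[k, 0], ok[k, 1]]), float(d[k])


def resolve_missing_climate(table: pd.DataFrame, waterbodies: WaterbodyConfig, rasters: xr.Dataset):
    """Fill missing covariates; idempotent; every fill tagged with its source.

    * missing SST + a waterbody id -> SST of the nearest non-missing raster
      cell at the waterbody's inlet location (tag ``inlet``);
    * any other missing covariate -> nearest non-missing raster cell to the
      record itself (tag ``nearest-cell``);
    * complete records pass through untouched (tag ``""``).
    """
    for var in RASTER_VAR_FOR_COLUMN.values():
        if var not in rasters:
            raise ValueError(f"rasters missing variable {var!r}")
        if np.isnan(rasters[var].values).all():
            raise ValueError(f"raster {var!r} entirely missing over the domain")

    out = table.copy()
    for col in RASTER_VAR_FOR_COLUMN:
        src_col = f"{col}_fill_source"
        if src_col not in out.columns:
            out[src_col] = ""

    inlet_cache = {}
    for idx in out.index:
        for col, var in RASTER_VAR_FOR_COLUMN.items():
            if not np.isnan(out.at[idx, col]):
                continue
            wid = str(out.at[idx, "waterbody_id"]) if "waterbody_id" in out.columns else ""
            if col == "SST" and wid not in ("", "nan"):
                if wid not in waterbodies.inlets:
                    raise ValueError(f"record {idx} references waterbody {wid!r} with no configured inlet")
                if wid not in inlet_cache:
                    ilon, ilat = waterbodies.inlets[wid]
                    inlet_cache[wid] = _nearest_cell_value(rasters[var], ilon, ilat)[0]
                out.at[idx, col] = inlet_cache[wid]
                out.at[idx, f"{col}_fill_source"] = "inlet"
            else:
                value, _ = _nearest_cell_value(rasters[var], float(out.at[idx, "lon"]), float(out.at[idx, "lat"]))
                out.at[idx, col] = value
                out.at[idx, f"{col}_fill_source"] = "nearest-cell"
    return out
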