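"""Source-to-destination connectivity from stranded trajectories.

Rows are release subregions (latitude bands labelled with the Florida /
Georgia coastal codes), columns are destination latitude bins.  Only
particles stranding on mangrove, salt-marsh or inlet cells count; urban
beach and other strandings are tallied separately so the audit

    matrix total + excluded strandings + expired + out_of_domain = released

always balances.  Destination bins are classified against the habitat
suitability maps as present-suitable, future-suitable under the
least-severe scenario that crosses the threshold, or unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import HABITAT_INLET, HABITAT_MANGROVE, HABITAT_SALTMARSH, HABITAT_NAMES, GridMask
from .lagrangian_tracker import STATUS_EXPIRED, STATUS_OUT_OF_DOMAIN, STATUS_STRANDED

#: Habitat classes whose strandings count toward connectivity.
COUNTED_HABITATS = (HABITAT_MANGROVE, HABITAT_SALTMARSH, HABITAT_INLET)

#: Default subregion latitude breaks (configurable; half-open intervals).
DEFAULT_SUBREGIONS = (
    ("SFL", 24.5, 26.5),
    ("CFL1", 26.5, 28.0),
    ("CFL2", 28.0, 29.0),
    ("NFL", 29.0, 30.7),
    ("GA", 30.7, 32.0),
)

DEFAULT_BIN_WIDTH = 0.1

CLASS_PRESENT = "present-suitable"
CLASS_UNSUITABLE = "unsuitable"


@dataclass(frozen=True)
class SubregionScheme:
    """Ordered, non-overlapping half-open latitude intervals with codes."""

    intervals: tuple = DEFAULT_SUBREGIONS

    def __post_init__(self):
        ivs = list(self.intervals)
        for code, lo, hi in ivs:
            if lo >= hi:
                raise ValueError(f"subregion {code}: empty interval")
        ordered = sorted(ivs, key=lambda t: t[1])
        for (c1, _, hi1), (c2, lo2, _) in zip(ordered, ordered[1:]):
            if lo2 < hi1:
                raise ValueError(f"subregions {c1} and {c2} overlap")
        object.__setattr__(self, "intervals", tuple(ordered))

    @property
    def codes(self):
        return [c for c, _, _ in self.intervals]

    def assign(self, lat: float) -> str:
        """Code of the interval containing lat; "none" outside the scheme.

        A latitude exactly on a break belongs to the upper interval
        (half-open [lo, hi) convention).
        """
        for code, lo, hi in self.intervals:
            if lo <= lat < hi:
                return code
        return "none"


def assign_subregion(lat: float, scheme: SubregionScheme) -> str:
    return scheme.assign(float(lat))


@dataclass
class ConnectivityMatrix:
    """Stranding counts: source subregions x destination latitude bins."""

    matrix: pd.DataFrame            # rows = codes (+ "none"), cols = bin lower edges
    bin_width: float
    exclusions: pd.DataFrame        # per-habitat-class excluded stranding tallies
    status_counts: dict             # stranded/expired/out_of_domain totals

    @property
    def total_counted(self) -> int:
        return int(self.matrix.to_numpy().sum())

    @property
    def total_excluded(self) -> int:
        return int(self.exclusions["count"].sum())

    def audit_balance(self) -> dict:
        """Conservation audit; 'residual' must be zero on every run."""
        released = sum(self.status_counts.values())
        residual = released - (
            self.total_counted
            + self.total_excluded
            + self.status_counts.get(STATUS_EXPIRED, 0)
            + self.status_counts.get(STATUS_OUT_OF_DOMAIN, 0)
        )
        return {
            "released": released,
            "counted": self.total_counted,
            "excluded": self.total_excluded,
            "expired": self.status_counts.get(STATUS_EXPIRED, 0),
            "out_of_domain": self.status_counts.get(STATUS_OUT_OF_DOMAIN, 0),
            "residual": residual,
        }


def build_connectivity(
    trajectories,
    scheme: SubregionScheme,
    mask: GridMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ConnectivityMatrix:
    """Count stranded particles by (release subregion, destination bin).

    Particles stranding on urban or unclassified coastal cells are excluded
    from the matrix but tallied, keeping the conservation audit exact.
    """
    spec = mask.spec
    edges = np.arange(spec.lat_min, spec.lat_max + bin_width / 2, bin_width)
    bin_lowers = np.round(edges[:-1], 6)
    codes = scheme.codes + ["none"]
    counts = pd.DataFrame(0, index=codes, columns=bin_lowers, dtype=int)
    excluded: dict = {}
    status_counts = {STATUS_STRANDED: 0, STATUS_EXPIRED: 0, STATUS_OUT_OF_DOMAIN: 0}

    for tr in trajectories:
        status_counts[tr.status] = status_counts.get(tr.status, 0) + 1
        if tr.status != STATUS_STRANDED:
            continue
        r, c = tr.stranding_cell
        if not mask.coastal[r, c]:
            raise ValueError(
                f"particle {tr.particle_id} records a non-coastal stranding cell {tr.stranding_cell}"
            )
        habitat = int(mask.habitat[r, c])
        if habitat not in COUNTED_HABITATS:
            name = HABITAT_NAMES.get(habitat, str(habitat))
            excluded[name] = excluded.get(name, 0) + 1
            continue
        src_lat = float(spec.lat_centers[tr.release_cell[0]])
        dest_lat = float(spec.lat_centers[r])
        row = scheme.assign(src_lat)
        b = int(np.floor((dest_lat - spec.lat_min) / bin_width))
        b = min(max(b, 0), len(bin_lowers) - 1)
        counts.loc[row, bin_lowers[b]] += 1

    exclusions = pd.DataFrame(
        [{"habitat": k, "count": v} for k, v in sorted(excluded.items())],
        columns=["habitat", "count"],
    )
    return ConnectivityMatrix(
        matrix=counts, bin_width=bin_width, exclusions=exclusions, status_counts=status_counts
    )


def classify_destination_suitability(
    bin_lowers,
    bin_width: float,
    scored_points: dict,
    thr: float,
    scenario_order,
) -> pd.DataFrame:
    """Class of each destination bin from the nearest scored wetland point.

    ``scored_points`` maps "present" and each scenario to a scored point
    table (columns lat, probability).  A bin inherits the class of its
    scored points (any point >= thr counts); bins containing no scored
    point are conservatively unsuitable.  Future-suitable bins are labelled
    with the least-severe scenario under which they cross the threshold.
    """
    if "present" not in scored_points:
        raise ValueError("scored_points must include the 'present' scenario")
    for scen in scenario_order:
        if scen not in scored_points:
            raise ValueError(f"missing scenario map: {scen}")
    rows = []
    for lo in bin_lowers:
        hi = lo + bin_width
        label = CLASS_UNSUITABLE
        present = scored_points["present"]
        sel = (present["lat"] >= lo) & (present["lat"] < hi)
        if sel.any() and (present.loc[sel, "probability"] >= thr).any():
            label = CLASS_PRESENT
        else:
            for scen in scenario_order:
                tab = scored_points[scen]
                sel = (tab["lat"] >= lo) & (tab["lat"] < hi)
                if sel.any() and (tab.loc[sel, "probability"] >= thr).any():
                    label = f"future-suitable:{scen}"
                    break
        rows.append({"bin_lower_lat": lo, "class": label})
    return pd.DataFrame(rows)


def northernmost_reached_suitable(matrix: ConnectivityMatrix, classes: pd.DataFrame, scenario: str | None = None):
    """Max destination-bin latitude with strandings and a suitable class.

    With ``scenario=None`` only present-suitable bins qualify; otherwise
    bins suitable presently or under any scenario up to and including the
    queried one qualify.  Returns NaN when no bin qualifies.
    """
    col_sums = matrix.matrix.sum(axis=0)
    cls = classes.set_index("bin_lower_lat")["class"]
    if not col_sums.index.equals(cls.index):
        raise ValueError("matrix columns and class table are not aligned")

    def qualifies(label: str) -> bool:
        if label == CLASS_PRESENT:
            return True
        if label.startswith("future-suitable:"):
            if scenario is None:
                return False
            return True if scenario == "any" else _scenario_rank(label.split(":", 1)[1]) <= _scenario_rank(scenario)
        return False

    best = float("nan")
    for lo, count in col_sums.items():
        if count > 0 and qualifies(cls[lo]):
            center = lo + matrix.bin_width / 2.0
            if np.isnan(best) or center > best:
                best = center
    return best


def _scenario_rank(scenario: str) -> int:
    from .synthetic_data import SCENARIOS

    try:
        return SCENARIOS.index(scenario)
    except ValueError:
        raise ValueError(f"unknown scenario {scenario!r}") from None
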