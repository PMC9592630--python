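"""Water-column fields: from sparse profile casts to gridded daily habitat masks.

Temperature is logged hourly at a handful of fixed depths; dissolved oxygen
(DO) is profiled on sparse dates at 1-m steps.  Both are linearly interpolated
onto a fine depth grid (0.1 m by default), temperature is averaged to daily
values, DO is linearly interpolated to daily values between cast dates, and
the two daily fields are combined into per-depth habitat masks under a
temperature ceiling and a DO floor.

The temperature exclusion is *top-down absolute*: every depth at or above the
deepest supra-threshold temperature is excluded, even if locally cool, because
a fish below cannot reach the surface without crossing warm water.  The DO
exclusion is cellwise, because hypoxia pools at the bottom and a mid-column
hypoxic lens only excludes itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HabitatBounds",
    "ProfileCast",
    "GriddedField",
    "default_depth_grid",
    "interpolate_vertical",
    "interpolate_temporal",
    "daily_mean",
    "isocline_depth",
    "habitat_mask",
    "read_profile_casts",
]

TEMPERATURE = "temperature_C"
DISSOLVED_OXYGEN = "do_mg_per_L"


def default_depth_grid(max_depth_m: float = 13.0, dz: float = 0.1) -> np.ndarray:
    """Depth grid 0.0..max_depth_m at dz steps (defaults match a 13-m column)."""
    n = int(round(max_depth_m / dz))
    return np.round(np.arange(n + 1) * dz, 6)


@dataclass(frozen=True)
class HabitatBounds:
    """Oxythermal habitat thresholds (deg C ceilings, mg/L floors).

    Defaults are the lake-whitefish bounds: usable habitat is < 14 deg C with
    > 2 mg/L DO; optimal habitat is < 10 deg C with > 4 mg/L DO.
    """

    t_usable: float = 14.0
    t_optimal: float = 10.0
    do_usable: float = 2.0
    do_optimal: float = 4.0

    def __post_init__(self) -> None:
        if not self.t_optimal < self.t_usable:
            raise ValueError("optimal temperature ceiling must be below usable")
        if not self.do_optimal > self.do_usable:
            raise ValueError("optimal DO floor must be above usable")

    def temp_limit(self, tier: str) -> float:
        return {"usable": self.t_usable, "optimal": self.t_optimal}[tier]

    def do_limit(self, tier: str) -> float:
        return {"usable": self.do_usable, "optimal": self.do_optimal}[tier]


@dataclass
class ProfileCast:
    """One vertical profile: (depth, value) samples at a single time."""

    timestamp: pd.Timestamp
    variable: str
    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.size == 0:
            raise ValueError("empty profile cast")
        if self.depths.shape != self.values.shape:
            raise ValueError("depths and values must have equal length")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("cast depths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cast values must be finite")
        if self.variable == DISSOLVED_OXYGEN and np.any(self.values < 0):
            raise ValueError("DO concentrations must be non-negative")


@dataclass
class GriddedField:
    """Depth x time raster of one variable on a regular depth grid.

    ``flags`` marks time steps whose column required edge-hold extrapolation
    (outside the cast span, single-sample casts, or partial days).
    """

    variable: str
    depths: np.ndarray
    times: pd.DatetimeIndex
    values: np.ndarray  # shape (n_depths, n_times)
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.depths.size, self.times.size):
            raise ValueError("values must have shape (n_depths, n_times)")
        if self.flags is None:
            self.flags = np.zeros(self.times.size, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def dz(self) -> float:
        return float(np.round(self.depths[1] - self.depths[0], 6))

    def column(self, when: pd.Timestamp) -> np.ndarray:
        """The depth column at an exact time-grid entry."""
        i = self.times.get_indexer([pd.Timestamp(when)])[0]
        if i < 0:
            raise KeyError(f"{when} not on the field's time grid")
        return self.values[:, i]

    def depth_index(self, depth_m: float) -> int:
        """Nearest-cell index for a depth (clipped to the grid)."""
        i = int(round((depth_m - self.depths[0]) / self.dz))
        return min(max(i, 0), self.depths.size - 1)

    def value_at(self, when: pd.Timestamp, depth_m: float) -> float:
        return float(self.column(when)[self.depth_index(depth_m)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: timestamp, depth_m, value."""
        t = np.repeat(self.times.values, self.depths.size)
        z = np.tile(self.depths, self.times.size)
        return pd.DataFrame(
            {"timestamp": t, "depth_m": z, "value": self.values.T.ravel()}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def interpolate_vertical(
    cast: ProfileCast, grid: np.ndarray | None = None, dz: float = 0.1
) -> tuple[np.ndarray, bool]:
    """Linearly interpolate a cast onto a regular depth grid.

    Piecewise-linear in depth and exact at sample depths.  Outside the cast's
    sampled range the edge value is held (no extrapolation) and the returned
    flag is set; a single-sample cast yields a constant column, flagged.
    """
    if grid is None:
        grid = default_depth_grid(dz=dz)
    grid = np.asarray(grid, dtype=float)
    flagged = bool(
        cast.depths.size < 2
        or grid[0] < cast.depths[0] - 1e-9
        or grid[-1] > cast.depths[-1] + 1e-9
    )
    return np.interp(grid, cast.depths, cast.values), flagged


def interpolate_temporal(
    casts: Sequence[ProfileCast],
    times: pd.DatetimeIndex | None = None,
    grid: np.ndarray | None = None,
    dz: float = 0.1,
) -> GriddedField:
    """Build a GriddedField from time-ordered casts of one variable.

    Each cast is gridded vertically, then each depth cell is linearly
    interpolated in time onto ``times`` (default: daily from the first to the
    last cast date).  Beyond the first/last cast the edge column is held and
    the time step flagged.
    """
    if len(casts) == 0:
        raise ValueError("no casts given")
    variable = casts[0].variable
    stamps = [c.timestamp for c in casts]
    if any(c.variable != variable for c in casts):
        raise ValueError("casts mix variables")
    if any(b <= a for a, b in zip(stamps, stamps[1:])):
        raise ValueError("casts must be strictly time-ordered")
    if grid is None:
        grid = default_depth_grid(dz=dz)
    cols, vflags = zip(*(interpolate_vertical(c, grid) for c in casts))
    cols = np.column_stack(cols)  # (n_depths, n_casts)

    if times is None:
        times = pd.date_range(stamps[0].normalize(), stamps[-1].normalize(), freq="D")
    times = pd.DatetimeIndex(times)
    t_casts = np.array([s.value for s in stamps], dtype=float)
    t_out = times.asi8.astype(float)
    values = np.empty((len(grid), len(times)))
    for i in range(len(grid)):
        values[i] = np.interp(t_out, t_casts, cols[i])
    edge = (t_out < t_casts[0]) | (t_out > t_casts[-1])
    # a flagged cast taints the interval it bounds
    cast_flag = np.interp(t_out, t_casts, np.asarray(vflags, dtype=float)) > 0
    return GriddedField(variable, grid, times, values, edge | cast_flag)


def daily_mean(hourly: GriddedField) -> GriddedField:
    """Collapse an hourly field to daily means per depth (local midnight days).

    Days covered by fewer than 24 hourly columns are averaged over the hours
    present and flagged.
    """
    dates = hourly.times.normalize()
    uniq = dates.unique().sort_values()
    values = np.empty((hourly.depths.size, uniq.size))
    flags = np.zeros(uniq.size, dtype=bool)
    for j, day in enumerate(uniq):
        sel = dates == day
        values[:, j] = hourly.values[:, sel].mean(axis=1)
        flags[j] = sel.sum() < 24 or hourly.flags[sel].any()
    return GriddedField(hourly.variable, hourly.depths, uniq, values, flags)


# ---------------------------------------------------------------------------
# isoclines and masks
# ---------------------------------------------------------------------------


def isocline_depth(
    column: np.ndarray, depths: np.ndarray, threshold: float, kind: str
) -> float:
    """Depth of a threshold crossing in a gridded column.

    ``kind='isotherm'``: deepest depth at which the value exceeds the
    threshold, linearly refined to the crossing below it (matching the
    top-down exclusion rule).  If no cell exceeds it, returns 0.0 (no warm
    exclusion); if every cell exceeds it, returns the bottom depth.

    ``kind='oxycline'``: shallowest depth at which the value falls below the
    threshold, linearly refined.  If no cell falls below, returns one grid
    step below the bottom (no hypoxic exclusion); if every cell does, 0.0.
    """
    column = np.asarray(column, dtype=float)
    depths = np.asarray(depths, dtype=float)
    step = depths[1] - depths[0] if depths.size > 1 else 0.1
    if kind == "isotherm":
        above = np.nonzero(column > threshold)[0]
        if above.size == 0:
            return 0.0
        i = above[-1]
        if i == column.size - 1:
            return float(depths[-1])
        return _cross(depths[i], depths[i + 1], column[i], column[i + 1], threshold)
    if kind == "oxycline":
        below = np.nonzero(column < threshold)[0]
        if below.size == 0:
            return float(depths[-1] + step)
        i = below[0]
        if i == 0:
            return 0.0
        return _cross(depths[i - 1], depths[i], column[i - 1], column[i], threshold)
    raise ValueError("kind must be 'isotherm' or 'oxycline'")


def _cross(z0: float, z1: float, v0: float, v1: float, threshold: float) -> float:
    if v0 == v1:
        return float(z1)
    return float(z0 + (v0 - threshold) / (v0 - v1) * (z1 - z0))


def habitat_mask(
    tcol: np.ndarray,
    docol: np.ndarray,
    bounds: HabitatBounds = HabitatBounds(),
    tier: str = "usable",
) -> np.ndarray:
    """Per-cell habitat mask for one day from daily T and DO columns.

    A cell is habitat iff it lies strictly below the deepest supra-threshold
    temperature cell (top-down exclusion) and its DO exceeds the tier's floor
    (cellwise exclusion).
    """
    tcol = np.asarray(tcol, dtype=float)
    docol = np.asarray(docol, dtype=float)
    if tcol.shape != docol.shape:
        raise ValueError("temperature and DO columns are on different grids")
    t_thr = bounds.temp_limit(tier)
    do_thr = bounds.do_limit(tier)
    warm = np.nonzero(tcol > t_thr)[0]
    ok_temp = np.ones(tcol.size, dtype=bool)
    if warm.size:
        ok_temp[: warm[-1] + 1] = False
    return ok_temp & (docol > do_thr)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_profile_casts(path: str | Path, variable: str) -> list[ProfileCast]:
    """Read a long-format `timestamp, depth_m, value` CSV into casts by time."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "depth_m", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    casts = []
    for stamp, grp in df.groupby("timestamp", sort=True):
        grp = grp.sort_values("depth_m")
        casts.append(
            ProfileCast(stamp, variable, grp["depth_m"].to_numpy(), grp["value"].to_numpy())
        )
    return casts
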