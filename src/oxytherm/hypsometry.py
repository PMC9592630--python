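"""Lake hypsography: the depth -> planar-area relationship.

All habitat budgeting reduces to integrals over this curve: the water volume
between two depths and the amount of lake bed ("benthic" area) between two
depths.  Planar area is taken to vary linearly with depth between tabulated
points, so both integrals have closed forms per segment and are exactly
additive over adjacent depth intervals.

Two readings of "lake-bottom area" are supported:

* ``planar_projection`` — the bed between z1 and z2 is the horizontal annulus
  A(z1) - A(z2); any residual flat bottom at the maximum depth is assigned
  there.  Total bed area then equals the surface area.
* ``frustum_slope_corrected`` — each depth band contributes its sloped
  (lateral) surface, computed from the band's perimeter; the perimeter is
  derived from the planar area via the shoreline-development ratio, so
  elongated or multi-basin lakes get a larger wetted bed than a circular
  lake of the same area.  Total bed area then slightly exceeds surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["HypsographicCurve", "lake658_like_hypsography"]

_MODES = ("planar_projection", "frustum_slope_corrected")


@dataclass
class HypsographicCurve:
    """Piecewise-linear depth -> planar-area curve for one lake.

    Parameters
    ----------
    depths
        Metres below surface, strictly increasing, starting at 0.
    planar_areas
        Horizontal cross-sectional area (m^2) at each depth; non-increasing.
    bed_area_mode
        One of ``planar_projection`` (default) or ``frustum_slope_corrected``.
    shore_development
        Shoreline-development ratio D >= 1: contour perimeter relative to a
        circle of equal area, P(z) = 2 D sqrt(pi A(z)).  Only used by the
        frustum mode.
    """

    depths: np.ndarray
    planar_areas: np.ndarray
    bed_area_mode: str = "planar_projection"
    shore_development: float = 1.0
    _cum_vol: np.ndarray = field(init=False, repr=False)
    _cum_lat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.planar_areas = np.asarray(self.planar_areas, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.planar_areas.shape:
            raise ValueError("depths and planar_areas must be 1-D and equal length")
        if len(self.depths) < 2:
            raise ValueError("need at least two tabulated depths")
        if self.depths[0] != 0.0:
            raise ValueError("depth table must start at the surface (0 m)")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(np.diff(self.planar_areas) > 1e-9):
            raise ValueError("planar areas must be non-increasing with depth")
        if self.planar_areas[-1] < 0:
            raise ValueError("planar areas must be non-negative")
        if self.bed_area_mode not in _MODES:
            raise ValueError(f"bed_area_mode must be one of {_MODES}")
        if self.shore_development < 1.0:
            raise ValueError("shore_development must be >= 1")
        # cumulative volume at nodes (trapezoid is exact for linear segments)
        dz = np.diff(self.depths)
        seg_vol = dz * (self.planar_areas[:-1] + self.planar_areas[1:]) / 2.0
        self._cum_vol = np.concatenate([[0.0], np.cumsum(seg_vol)])
        self._cum_lat = np.concatenate([[0.0], np.cumsum(self._segment_lateral())])

    # ------------------------------------------------------------------ basic
    @property
    def max_depth(self) -> float:
        return float(self.depths[-1])

    def area_at(self, z: float | np.ndarray) -> float | np.ndarray:
        """Planar cross-sectional area (m^2) at depth z, linearly interpolated."""
        self._check_depth(np.min(z))
        self._check_depth(np.max(z))
        out = np.interp(z, self.depths, self.planar_areas)
        return float(out) if np.isscalar(z) else out

    def total_volume(self) -> float:
        return float(self._cum_vol[-1])

    def total_bed_area(self) -> float:
        return self.bed_area_between(0.0, self.max_depth)

    # -------------------------------------------------------------- integrals
    def volume_between(self, z1: float, z2: float) -> float:
        """Water volume (m^3) between depths z1 <= z2."""
        self._check_pair(z1, z2)
        return self._cum_volume(z2) - self._cum_volume(z1)

    def bed_area_between(self, z1: float, z2: float) -> float:
        """Lake-bed area (m^2) between depths z1 <= z2.

        The flat terminal bottom (planar area remaining at maximum depth) is
        assigned to intervals that reach the maximum depth, in both modes.
        """
        self._check_pair(z1, z2)
        if z2 <= z1:
            return 0.0
        bottom = self.planar_areas[-1] if z2 >= self.max_depth else 0.0
        if self.bed_area_mode == "planar_projection":
            return float(self.area_at(z1) - self.area_at(z2) + bottom)
        return self._cum_lateral(z2) - self._cum_lateral(z1) + float(bottom)

    # ------------------------------------------------------------- grid cells
    def cell_volumes(self, grid: np.ndarray) -> np.ndarray:
        """Volumes of half-open cells [z_i, z_{i+1}); the last cell extends to
        the maximum depth so the cells partition the whole lake."""
        edges = self._cell_edges(grid)
        return np.array([self.volume_between(a, b) for a, b in zip(edges[:-1], edges[1:])])

    def cell_bed_areas(self, grid: np.ndarray) -> np.ndarray:
        edges = self._cell_edges(grid)
        return np.array([self.bed_area_between(a, b) for a, b in zip(edges[:-1], edges[1:])])

    def _cell_edges(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if grid[0] < 0 or grid[-1] > self.max_depth:
            raise ValueError("grid outside the curve's depth range")
        return np.concatenate([grid, [self.max_depth]])

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "HypsographicCurve":
        """Read a `depth_m, planar_area_m2` CSV (header required, depth ascending)."""
        df = pd.read_csv(path)
        missing = {"depth_m", "planar_area_m2"} - set(df.columns)
        if missing:
            raise ValueError(f"hypsography CSV missing columns: {sorted(missing)}")
        return cls(df["depth_m"].to_numpy(), df["planar_area_m2"].to_numpy(), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"depth_m": self.depths, "planar_area_m2": self.planar_areas}
        ).to_csv(path, index=False)

    # -------------------------------------------------------------- internals
    def _check_depth(self, z: float) -> None:
        if z < -1e-9 or z > self.max_depth + 1e-9:
            raise ValueError(f"depth {z} outside [0, {self.max_depth}]")

    def _check_pair(self, z1: float, z2: float) -> None:
        self._check_depth(z1)
        self._check_depth(z2)
        if z1 > z2:
            raise ValueError(f"expected z1 <= z2, got {z1} > {z2}")

    def _cum_volume(self, z: float) -> float:
        i = int(np.searchsorted(self.depths, z, side="right")) - 1
        i = min(max(i, 0), len(self.depths) - 2)
        a_z = np.interp(z, self.depths, self.planar_areas)
        partial = (z - self.depths[i]) * (self.planar_areas[i] + a_z) / 2.0
        return float(self._cum_vol[i] + partial)

    def _segment_lateral(self) -> np.ndarray:
        """Exact lateral bed area of each tabulated segment (frustum mode)."""
        return np.array(
            [
                self._lateral_integral(self.depths[i], self.depths[i + 1])
                for i in range(len(self.depths) - 1)
            ]
        )

    def _lateral_integral(self, za: float, zb: float) -> float:
        """Integral of sqrt((dA/dz)^2 + P(z)^2) dz over [za, zb] within one
        tabulated segment, with P(z) = 2 D sqrt(pi A(z)) and A linear in z."""
        if zb <= za:
            return 0.0
        i = int(np.searchsorted(self.depths, za, side="right")) - 1
        i = min(max(i, 0), len(self.depths) - 2)
        z0, z1 = self.depths[i], self.depths[i + 1]
        a0, a1 = self.planar_areas[i], self.planar_areas[i + 1]
        m = (a1 - a0) / (z1 - z0)  # dA/dz, <= 0
        d2 = 4.0 * np.pi * self.shore_development**2
        # integrand^2 = m^2 + d2 * A(z), A(z) = a0 + m (z - z0): linear in z
        alpha = m * m + d2 * (a0 + m * (za - z0))
        beta = d2 * m
        if abs(beta) < 1e-12:
            return float(np.sqrt(alpha) * (zb - za))
        hi = alpha + beta * (zb - za)
        return float((2.0 / (3.0 * beta)) * (hi ** 1.5 - alpha ** 1.5))

    def _cum_lateral(self, z: float) -> float:
        i = int(np.searchsorted(self.depths, z, side="right")) - 1
        i = min(max(i, 0), len(self.depths) - 2)
        return float(self._cum_lat[i] + self._lateral_integral(self.depths[i], z))


def lake658_like_hypsography(
    surface_area_m2: float = 84_000.0,
    target_volume_m3: float = 547_966.0,
    target_bed_area_m2: float = 86_227.0,
    max_depth_m: float = 13.3,
    east_basin_depth_m: float = 11.3,
    dz: float = 0.1,
) -> HypsographicCurve:
    """Synthetic hypsography emulating a small double-basin boreal lake.

    The real lake's depth-area table is not public, so this builds a two-basin
    bowl (deep basin to ``max_depth_m``, secondary basin to
    ``east_basin_depth_m``) fronted by a littoral shelf, then calibrates one
    shape weight so the total volume matches ``target_volume_m3`` and the
    shoreline-development ratio so the slope-corrected bed area matches
    ``target_bed_area_m2``.  The shelf is deliberately heavy: confining
    habitat to deep water costs proportionally more lake bed than lake
    volume, the regime the habitat-budget analyses are designed around.
    """
    z = np.round(np.arange(0.0, max_depth_m + dz / 2, dz), 6)
    if z[-1] < max_depth_m:
        z = np.append(z, max_depth_m)

    # Steep littoral shelf over a steep-walled double basin: the main basin
    # keeps nearly constant area until a plunge near the maximum depth, the
    # secondary basin bottoms out shallower.  This concentrates bed area in
    # the littoral zone so that deep-confined habitat keeps a smaller bed
    # fraction than volume fraction (only geometrically possible down to
    # z* ~ max_depth - mean_depth; see the methods note).
    shelf = np.exp(-z / 2.0)

    def plunge(z_flat: float, zmax: float) -> np.ndarray:
        frac = np.clip((z - z_flat) / (zmax - z_flat), 0.0, 1.0)
        return 1.0 - frac**2

    core = 0.75 * plunge(max_depth_m - 1.8, max_depth_m) + 0.25 * plunge(
        east_basin_depth_m - 1.8, east_basin_depth_m
    )

    def shape(w: float) -> np.ndarray:
        g = w * shelf + (1.0 - w) * core
        return surface_area_m2 * g / g[0]

    def volume(w: float) -> float:
        areas = shape(w)
        return float(np.trapezoid(areas, z))

    lo, hi = 0.0, 0.9  # volume(w) decreases with w (shelf holds little water)
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if volume(mid) > target_volume_m3:
            lo = mid
        else:
            hi = mid
    areas = shape((lo + hi) / 2.0)

    # calibrate shoreline development so the frustum bed area hits the target
    d_lo, d_hi = 1.0, 12.0
    for _ in range(80):
        d_mid = (d_lo + d_hi) / 2.0
        curve = HypsographicCurve(
            z, areas, bed_area_mode="frustum_slope_corrected", shore_development=d_mid
        )
        if curve.total_bed_area() < target_bed_area_m2:
            d_lo = d_mid
        else:
            d_hi = d_mid
    return HypsographicCurve(
        z,
        areas,
        bed_area_mode="frustum_slope_corrected",
        shore_development=(d_lo + d_hi) / 2.0,
    )
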