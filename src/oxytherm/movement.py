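"""Per-fish daily movement metrics from filtered telemetry.

Vertical movement comes from the pressure-sensor depth stream (sum of
absolute depth changes between successive detections); lateral movement from
the positioning-system stream (sum of haversine distances).  The two streams
are processed separately, as positions are resolved independently of depth
pings.  Because each inter-detection distance is a straight-line lower bound,
daily totals are *minimum* distances moved.

Swim speed is normalised by body size: per pair, (distance / seconds) * 60 /
total length, in body lengths per minute; the daily figure is the mean of
per-pair speeds (not total distance over total time).

A day's vertical total can be read as a foray count: one foray is one
down-and-up traverse of the occupied depth band, so forays ~= total / (2 *
band width).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "vertical_total",
    "lateral_total",
    "pair_speeds",
    "foray_estimate",
    "daily_movement",
    "attach_category",
]

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between coordinate pairs (degrees)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def vertical_total(depths: np.ndarray) -> float:
    """Sum of absolute depth changes over successive detections (m)."""
    depths = np.asarray(depths, dtype=float)
    if depths.size < 2:
        return 0.0
    return float(np.abs(np.diff(depths)).sum())


def lateral_total(lats: np.ndarray, lons: np.ndarray) -> float:
    """Sum of successive great-circle distances (m); NaN positions skipped."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    ok = np.isfinite(lats) & np.isfinite(lons)
    lats, lons = lats[ok], lons[ok]
    if lats.size < 2:
        return 0.0
    return float(haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:]).sum())


def pair_speeds(
    distances_m: np.ndarray, dt_s: np.ndarray, total_length_m: float
) -> np.ndarray:
    """Per-pair swim speeds in body lengths per minute; zero-dt pairs dropped."""
    if total_length_m <= 0:
        raise ValueError("total length must be positive")
    distances_m = np.asarray(distances_m, dtype=float)
    dt_s = np.asarray(dt_s, dtype=float)
    ok = dt_s > 0
    return distances_m[ok] / dt_s[ok] * 60.0 / total_length_m


def foray_estimate(daily_vertical_total_m: float, band_top_m: float, band_bottom_m: float) -> int:
    """Daily vertical total expressed as down-and-up traverses of a depth band."""
    width = band_bottom_m - band_top_m
    if width <= 0:
        raise ValueError("band bottom must lie below band top")
    return int(round(daily_vertical_total_m / (2.0 * width)))


def _daily_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Successive-detection pairs of one fish with both ends on the same local
    day; midnight-straddling pairs are excluded."""
    df = df.sort_values("timestamp", kind="stable")
    t = df["timestamp"].reset_index(drop=True)
    same_day = t.dt.normalize().iloc[1:].to_numpy() == t.dt.normalize().iloc[:-1].to_numpy()
    out = pd.DataFrame(
        {
            "date": t.dt.normalize().iloc[:-1].to_numpy(),
            "dt_s": (t.iloc[1:].to_numpy() - t.iloc[:-1].to_numpy())
            .astype("timedelta64[ns]")
            .astype("int64")
            / 1e9,
        }
    )
    for col in ("depth_m", "lat", "lon"):
        if col in df.columns:
            v = df[col].reset_index(drop=True)
            out[f"{col}_a"] = v.iloc[:-1].to_numpy()
            out[f"{col}_b"] = v.iloc[1:].to_numpy()
    return out[same_day]


def daily_movement(
    depth_stream: pd.DataFrame,
    position_stream: pd.DataFrame | None,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-fish per-day movement table.

    ``depth_stream`` needs `timestamp, fish_id, depth_m`; ``position_stream``
    (optional) needs `timestamp, fish_id, lat, lon`.  Returns one row per fish
    and day present in either stream with columns `fish_id, date,
    vertical_total_m, lateral_total_m, vertical_speed_blmin,
    lateral_speed_blmin, n_pairs, n_lateral_pairs`.  Days with fewer than two
    detections contribute zero totals; speeds are NaN when no valid pair
    exists.
    """
    lengths = meta.set_index("fish_id")["total_length_mm"] / 1000.0
    records: dict[tuple[str, pd.Timestamp], dict] = {}

    def rec(fish: str, date: pd.Timestamp) -> dict:
        return records.setdefault(
            (fish, date),
            {
                "vertical_total_m": 0.0,
                "lateral_total_m": 0.0,
                "vertical_speed_blmin": np.nan,
                "lateral_speed_blmin": np.nan,
                "n_pairs": 0,
                "n_lateral_pairs": 0,
            },
        )

    for fish, grp in depth_stream.groupby("fish_id", sort=True):
        length = float(lengths.get(fish, np.nan))
        for date, day in _daily_pairs(grp).groupby("date"):
            r = rec(fish, date)
            dist = np.abs(day["depth_m_b"].to_numpy() - day["depth_m_a"].to_numpy())
            r["vertical_total_m"] = float(dist.sum())
            r["n_pairs"] = int(len(day))
            if np.isfinite(length):
                speeds = pair_speeds(dist, day["dt_s"].to_numpy(), length)
                if speeds.size:
                    r["vertical_speed_blmin"] = float(speeds.mean())

    if position_stream is not None and len(position_stream):
        for fish, grp in position_stream.groupby("fish_id", sort=True):
            length = float(lengths.get(fish, np.nan))
            grp = grp.dropna(subset=["lat", "lon"])
            for date, day in _daily_pairs(grp).groupby("date"):
                r = rec(fish, date)
                dist = haversine_m(
                    day["lat_a"].to_numpy(),
                    day["lon_a"].to_numpy(),
                    day["lat_b"].to_numpy(),
                    day["lon_b"].to_numpy(),
                )
                r["lateral_total_m"] = float(dist.sum())
                r["n_lateral_pairs"] = int(len(day))
                if np.isfinite(length):
                    speeds = pair_speeds(dist, day["dt_s"].to_numpy(), length)
                    if speeds.size:
                        r["lateral_speed_blmin"] = float(speeds.mean())

    rows = [
        {"fish_id": fish, "date": date, **vals}
        for (fish, date), vals in sorted(records.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id",
            "date",
            "vertical_total_m",
            "lateral_total_m",
            "vertical_speed_blmin",
            "lateral_speed_blmin",
            "n_pairs",
            "n_lateral_pairs",
        ],
    )


def attach_category(daily: pd.DataFrame, budgets: pd.DataFrame) -> pd.DataFrame:
    """Join each movement day with its habitat-constraint category — the tidy
    table exported for external mixed-model / GAM fitting."""
    cat = budgets[["date", "category", "excluded"]]
    return daily.merge(cat, on="date", how="left")
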