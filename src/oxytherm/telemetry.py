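"""Acoustic-telemetry ingest: parse, filter, annotate, and tabulate detections.

Depth-coded transmitters ping every 60-180 s; overlapping receivers log the
same ping more than once, so the stream is thinned per fish to >= ``min_gap_s``
between *kept* detections.  Records deeper than the sensor's plausible range,
with unknown fish IDs, or before each fish's post-surgery cutoff date are
dropped.  Hyperbolic positioning error (HPE) above the threshold is reported
but never filtered.

Kept detections are annotated with the ambient temperature (hourly field) and
DO (daily field) at the nearest 0.1-m cell, from which occupancy tables count
the share of detections inside / too warm for / too oxygen-poor for each
habitat tier.  The two suboptimal columns may overlap (a detection can be both
warm and hypoxic), so the reported overlap closes the accounting identity
inside + warm + lowDO - both = 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .limnofield import GriddedField, HabitatBounds

__all__ = [
    "FilterReport",
    "WINDOW_PRESETS",
    "read_detections",
    "read_fish_meta",
    "filter_detections",
    "annotate_environment",
    "occupancy_table",
]

# Twenty-day analysis windows, one per constraint category of the study year.
WINDOW_PRESETS: dict[str, tuple[str, str]] = {
    "moderate": ("2015-05-23", "2015-06-11"),
    "high": ("2015-07-23", "2015-08-11"),
    "severe": ("2015-09-17", "2015-10-06"),
    "low": ("2016-01-23", "2016-02-11"),
}


@dataclass(frozen=True)
class FilterReport:
    """Accounting for one pass of :func:`filter_detections`."""

    n_raw: int
    n_unknown_id: int
    n_pre_cutoff: int
    n_depth_dropped: int
    n_duplicates: int
    n_after_dedupe: int
    hpe_gt_threshold_frac: float

    def __post_init__(self) -> None:
        total = (
            self.n_unknown_id
            + self.n_pre_cutoff
            + self.n_depth_dropped
            + self.n_duplicates
            + self.n_after_dedupe
        )
        if total != self.n_raw:
            raise ValueError("filter counts do not add up to the raw count")


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detection CSV: `timestamp, fish_id, depth_m[, lat, lon, hpe]`.

    Timestamps are ISO-8601 local (naive) time.  Rows whose timestamp or depth
    fail to parse are dropped and counted in the returned frame's
    ``attrs['n_unparseable']`` rather than raising.
    """
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = {"timestamp", "fish_id", "depth_m"} - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    df["depth_m"] = pd.to_numeric(df["depth_m"], errors="coerce")
    df = df.dropna(subset=["timestamp", "depth_m"]).reset_index(drop=True)
    df.attrs["n_unparseable"] = n0 - len(df)
    return df


def read_fish_meta(path: str | Path) -> pd.DataFrame:
    """Read fish metadata: `fish_id, total_length_mm, cutoff_date`."""
    df = pd.read_csv(path, dtype={"fish_id": str}, parse_dates=["cutoff_date"])
    missing = {"fish_id", "total_length_mm", "cutoff_date"} - set(df.columns)
    if missing:
        raise ValueError(f"fish metadata CSV missing columns: {sorted(missing)}")
    if (df["total_length_mm"] <= 0).any():
        raise ValueError("total length must be positive")
    return df


def filter_detections(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    min_gap_s: float = 60.0,
    max_depth_m: float = 14.0,
    hpe_threshold: float = 20.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard detection filters; HPE is reported, not filtered.

    Order: unknown fish ID, pre-cutoff, implausible depth, then per-fish
    dedupe.  A detection is a duplicate when its gap to the *last kept*
    detection of the same fish is below ``min_gap_s``, which thins the stream
    to at least that spacing.  The ID/cutoff/depth filters commute with each
    other; dedupe is applied last (its result depends on what survives the
    other filters).
    """
    if len(raw) == 0:
        return raw.copy(), FilterReport(0, 0, 0, 0, 0, 0, 0.0)
    df = raw.sort_values(["timestamp"], kind="stable").reset_index(drop=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    n_raw = len(df)

    known = set(meta["fish_id"])
    ok_id = df["fish_id"].isin(known)
    n_unknown = int((~ok_id).sum())
    df = df[ok_id]

    cutoff = meta.set_index("fish_id")["cutoff_date"]
    ok_cut = df["timestamp"] >= df["fish_id"].map(cutoff)
    n_pre = int((~ok_cut).sum())
    df = df[ok_cut]

    if "depth_m" in df.columns:
        ok_depth = df["depth_m"] <= max_depth_m
        n_depth = int((~ok_depth).sum())
        df = df[ok_depth]
    else:  # e.g. the positioning-system stream carries no depth
        n_depth = 0
    df = df.reset_index(drop=True)

    keep = np.ones(len(df), dtype=bool)
    t = df["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64")
    gap_ns = int(min_gap_s * 1e9)
    for _, idx in df.groupby("fish_id", sort=False).indices.items():
        last = -(1 << 62)
        for i in idx:
            if t[i] - last < gap_ns:
                keep[i] = False
            else:
                last = t[i]
    n_dup = int((~keep).sum())
    kept = df[keep].reset_index(drop=True)

    if "hpe" in kept.columns and kept["hpe"].notna().any():
        hpe = kept["hpe"].dropna()
        hpe_frac = float((hpe > hpe_threshold).mean())
    else:
        hpe_frac = 0.0

    report = FilterReport(
        n_raw=n_raw,
        n_unknown_id=n_unknown,
        n_pre_cutoff=n_pre,
        n_depth_dropped=n_depth,
        n_duplicates=n_dup,
        n_after_dedupe=len(kept),
        hpe_gt_threshold_frac=hpe_frac,
    )
    return kept, report


def annotate_environment(
    kept: pd.DataFrame,
    t_hourly: GriddedField,
    do_daily: GriddedField,
    t_daily: GriddedField | None = None,
) -> pd.DataFrame:
    """Attach ambient conditions at each detection's depth.

    ``ambient_temp`` comes from the hourly temperature field at the detection
    hour; ``ambient_do`` from the daily DO field at the detection date; both
    use the nearest 0.1-m depth cell (the fields are already gridded, so no
    re-interpolation).  If ``t_daily`` is given, ``ambient_temp_daily`` is
    added as well — the combined oxythermal accounting matches temperature to
    the daily resolution of the DO data.  Detections outside field coverage
    get NaN and ``coverage_flag=True``; occupancy statistics skip them.
    """
    out = kept.copy()
    hours = out["timestamp"].dt.floor("h")
    days = out["timestamp"].dt.normalize()

    h_idx = t_hourly.times.get_indexer(hours)
    d_idx = do_daily.times.get_indexer(days)
    z_t = np.clip(
        np.round((out["depth_m"].to_numpy() - t_hourly.depths[0]) / t_hourly.dz),
        0,
        t_hourly.depths.size - 1,
    ).astype(int)
    z_d = np.clip(
        np.round((out["depth_m"].to_numpy() - do_daily.depths[0]) / do_daily.dz),
        0,
        do_daily.depths.size - 1,
    ).astype(int)

    temp = np.where(h_idx >= 0, t_hourly.values[z_t, np.clip(h_idx, 0, None)], np.nan)
    do = np.where(d_idx >= 0, do_daily.values[z_d, np.clip(d_idx, 0, None)], np.nan)
    out["ambient_temp"] = temp
    out["ambient_do"] = do
    out["coverage_flag"] = (h_idx < 0) | (d_idx < 0)
    if t_daily is not None:
        td_idx = t_daily.times.get_indexer(days)
        z_td = np.clip(
            np.round((out["depth_m"].to_numpy() - t_daily.depths[0]) / t_daily.dz),
            0,
            t_daily.depths.size - 1,
        ).astype(int)
        out["ambient_temp_daily"] = np.where(
            td_idx >= 0, t_daily.values[z_td, np.clip(td_idx, 0, None)], np.nan
        )
        out["coverage_flag"] |= td_idx < 0
    return out


def occupancy_table(
    annotated: pd.DataFrame,
    bounds: HabitatBounds = HabitatBounds(),
    window: tuple[str, str] | None = None,
    temp_col: str = "ambient_temp",
    do_col: str = "ambient_do",
) -> pd.DataFrame:
    """Percent of detections inside / too warm / too low-DO per habitat tier.

    ``inside`` requires both conditions met (T <= ceiling and DO >= floor);
    ``warm`` and ``low_do`` are each condition's violations and may overlap,
    with the overlap in ``both`` so that inside + warm + low_do - both = 100.
    """
    df = annotated
    if window is not None:
        a, b = (pd.Timestamp(x) for x in window)
        days = df["timestamp"].dt.normalize()
        df = df[(days >= a) & (days <= b)]
    if "coverage_flag" in df.columns:
        df = df[~df["coverage_flag"]]
    df = df.dropna(subset=[temp_col, do_col])
    if len(df) == 0:
        raise ValueError("no annotated detections in the requested window")
    rows = []
    for tier in ("usable", "optimal"):
        warm = df[temp_col] > bounds.temp_limit(tier)
        low = df[do_col] < bounds.do_limit(tier)
        rows.append(
            {
                "tier": tier,
                "n": len(df),
                "inside_pct": 100.0 * float((~warm & ~low).mean()),
                "warm_pct": 100.0 * float(warm.mean()),
                "low_do_pct": 100.0 * float(low.mean()),
                "both_pct": 100.0 * float((warm & low).mean()),
            }
        )
    return pd.DataFrame(rows)
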