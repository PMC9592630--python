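#!/usr/bin/env python
"""Daily movement metrics for the four 20-d constraint windows.

Computes per-fish daily vertical and lateral totals and body-length swim
speeds from the filtered depth and position streams, joins the daily
constraint category, summarises each window, and expresses the
high-constraint vertical travel as a daily foray count through the occupied
depth band.  Writes results/movement_windows.csv (fish-day rows, model-ready)
and results/movement_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import oxytherm as ox
from oxytherm.movement import foray_estimate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "detections.csv").exists():
        raise SystemExit("scenario inputs missing - run analysis/01_simulate.py first")
    raw = ox.read_detections(SCRATCH / "detections.csv")
    positions = pd.read_csv(SCRATCH / "positions.csv", parse_dates=["timestamp"],
                            dtype={"fish_id": str})
    meta = ox.read_fish_meta(SCRATCH / "fish_meta.csv")
    kept, _ = ox.filter_detections(raw, meta)
    pos_kept, _ = ox.filter_detections(positions, meta)

    budgets = pd.read_csv(RESULTS / "habitat_budget.csv", parse_dates=["date"])
    budgets["excluded"] = False

    frames = []
    for name, (a, b) in ox.WINDOW_PRESETS.items():
        sel = lambda df: df[(df["timestamp"] >= pd.Timestamp(a))
                            & (df["timestamp"] < pd.Timestamp(b) + pd.Timedelta(days=1))]
        daily = ox.daily_movement(sel(kept), sel(pos_kept), meta)
        daily.insert(0, "window", name)
        frames.append(daily)
    movement = pd.concat(frames, ignore_index=True)
    movement = ox.attach_category(movement, budgets).drop(columns="excluded")
    movement.to_csv(RESULTS / "movement_windows.csv", index=False)

    summary = (
        movement.groupby("window", sort=False)
        .agg(
            vertical_m_day=("vertical_total_m", "mean"),
            lateral_m_day=("lateral_total_m", "mean"),
            vertical_blmin=("vertical_speed_blmin", "mean"),
            lateral_blmin=("lateral_speed_blmin", "mean"),
            fish_days=("date", "size"),
        )
        .round(2)
    )
    summary.to_csv(RESULTS / "movement_summary.csv")
    print("window means (per fish-day):")
    print(summary.to_string())

    high = movement[movement["window"] == "high"]
    a, b = ox.WINDOW_PRESETS["high"]
    in_window = kept[(kept["timestamp"] >= pd.Timestamp(a))
                     & (kept["timestamp"] < pd.Timestamp(b) + pd.Timedelta(days=1))]
    q1, q3 = in_window["depth_m"].quantile([0.25, 0.75])
    forays = foray_estimate(high["vertical_total_m"].mean(), q1, q3)
    print(f"\nhigh-constraint occupied band (IQR): {q1:.1f}-{q3:.1f} m")
    print(f"mean vertical travel {high['vertical_total_m'].mean():.1f} m/day "
          f"~= {forays} forays/day through that band")
    print(f"-> {RESULTS/'movement_windows.csv'}")


if __name__ == "__main__":
    main()
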