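#!/usr/bin/env python
"""Filter the detection log and tabulate habitat occupancy per 20-d window.

Applies the standard filters (unknown ID, post-surgery cutoff, >14 m depth,
60-s dedupe; HPE reported only), annotates each kept detection with ambient
temperature and DO, and computes the percent of detections inside / too warm
for / too oxygen-poor for usable and optimal habitat in each 20-day
constraint window.  Writes results/occupancy.csv and
results/filter_report.csv.
"""

from pathlib import Path

import pandas as pd

import oxytherm as ox
from oxytherm.limnofield import DISSOLVED_OXYGEN, TEMPERATURE

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

    kept, report = ox.filter_detections(raw, meta)
    hpe_frac = (positions["hpe"] > 20).mean()
    print(f"raw detections: {report.n_raw:,}")
    print(f"  dropped: {report.n_pre_cutoff:,} pre-cutoff, "
          f"{report.n_depth_dropped:,} deep, {report.n_unknown_id:,} unknown ID, "
          f"{report.n_duplicates:,} duplicates (<60 s)")
    print(f"  kept: {report.n_after_dedupe:,}; HPE>20 in positions: {100*hpe_frac:.1f}% "
          "(reported, not filtered)")
    pd.DataFrame([{**report.__dict__, "hpe_gt20_positions_frac": hpe_frac}]).to_csv(
        RESULTS / "filter_report.csv", index=False)

    t_casts = ox.limnofield.read_profile_casts(
        SCRATCH / "temperature_hourly.csv", TEMPERATURE)
    hours = pd.DatetimeIndex([c.timestamp for c in t_casts])
    t_hourly = ox.interpolate_temporal(t_casts, times=hours)
    t_daily = ox.daily_mean(t_hourly)
    do_daily = ox.interpolate_temporal(
        ox.limnofield.read_profile_casts(SCRATCH / "do_casts.csv", DISSOLVED_OXYGEN),
        times=t_daily.times)
    annotated = ox.annotate_environment(kept, t_hourly, do_daily, t_daily)

    tables = []
    for name, window in ox.WINDOW_PRESETS.items():
        table = ox.occupancy_table(annotated, window=window,
                                   temp_col="ambient_temp_daily")
        table.insert(0, "window", name)
        tables.append(table)
    occupancy = pd.concat(tables, ignore_index=True)
    occupancy.to_csv(RESULTS / "occupancy.csv", index=False)
    print("\npercent of detections per 20-d window "
          "(inside / too-warm / low-DO; suboptimal columns may overlap):")
    print(occupancy.round(1).to_string(index=False))
    print(f"-> {RESULTS/'occupancy.csv'}")


if __name__ == "__main__":
    main()
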