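#!/usr/bin/env python
"""Daily oxythermal habitat budget for the simulated study year.

Reads the scenario CSVs written by 01_simulate.py, rebuilds the gridded
temperature and DO fields exactly as the pipeline would from logger/cast
files, and computes the daily usable/optimal volume and bed-area fractions,
constraint categories, and the annual summary.  Writes
results/habitat_budget.csv and results/annual_summary.csv.
"""

from pathlib import Path

import pandas as pd

import oxytherm as ox
from oxytherm.limnofield import DISSOLVED_OXYGEN, TEMPERATURE

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"

TURNOVER_WINDOW = ("2015-10-09", "2015-10-22")  # rapid-change exclusion


def main() -> None:
    if not (SCRATCH / "temperature_hourly.csv").exists():
        raise SystemExit("scenario inputs missing - run analysis/01_simulate.py first")
    curve = ox.HypsographicCurve.from_csv(
        RESULTS / "hypsography.csv",
        bed_area_mode="frustum_slope_corrected",
        shore_development=ox.lake658_like_hypsography().shore_development,
    )
    t_casts = ox.limnofield.read_profile_casts(
        SCRATCH / "temperature_hourly.csv", TEMPERATURE)
    do_casts = ox.limnofield.read_profile_casts(SCRATCH / "do_casts.csv", DISSOLVED_OXYGEN)
    print(f"{len(t_casts)} hourly temperature columns, {len(do_casts)} DO casts")

    hours = pd.DatetimeIndex([c.timestamp for c in t_casts])
    t_hourly = ox.interpolate_temporal(t_casts, times=hours)
    t_daily = ox.daily_mean(t_hourly)
    do_daily = ox.interpolate_temporal(do_casts, times=t_daily.times)

    budgets = ox.compute_budgets(t_daily, do_daily, curve, exclude=TURNOVER_WINDOW)
    ox.habitat_budget.write_budget_csv(budgets, RESULTS / "habitat_budget.csv")

    summary = ox.annual_summary(budgets, t_daily, do_daily, curve)
    pd.DataFrame([summary.__dict__]).to_csv(RESULTS / "annual_summary.csv", index=False)

    counts = budgets.loc[~budgets["excluded"], "category"].value_counts()
    print("constraint-category days (turnover window excluded):")
    print(counts.to_string())
    print(f"days without optimal habitat: {summary.days_absent_optimal}")
    print(f"days without usable habitat:  {summary.days_absent_usable}")
    print(f"minimum usable habitat: {100*summary.min_usable_volume_frac:.1f}% of volume, "
          f"{100*budgets['usable_bed_frac'].min():.1f}% of bed area")
    print(f"-> {RESULTS/'habitat_budget.csv'}")


if __name__ == "__main__":
    main()
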