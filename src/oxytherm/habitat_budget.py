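"""Daily oxythermal habitat budgets over a lake's hypsography.

A day's habitat mask (from :mod:`oxytherm.limnofield`) is converted into the
fraction of lake volume and lake-bed area it occupies, the day is classified
into a constraint category from the optimal bed fraction, and a season of
budgets is condensed into an annual summary (days without habitat, minima,
and the signed both-suboptimal convention for years that lose all habitat).

Constraint categories follow the bed-area thresholds used for benthic
coldwater fish: ``low`` > 50 %, ``moderate`` (10, 50] %, ``high`` [1, 10] %,
``severe`` < 1 % of lake-bed area in optimal habitat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hypsometry import HypsographicCurve
from .limnofield import GriddedField, HabitatBounds, habitat_mask

__all__ = [
    "AnnualSummary",
    "cell_weights",
    "daily_budget",
    "classify_constraint",
    "compute_budgets",
    "annual_summary",
    "write_budget_csv",
]

CATEGORIES = ("low", "moderate", "high", "severe")


def cell_weights(
    curve: HypsographicCurve, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Volume and bed area of each half-open depth cell [z_i, z_{i+1}).

    The last cell extends to the lake's maximum depth, so the weights sum to
    the lake totals exactly.
    """
    return curve.cell_volumes(grid), curve.cell_bed_areas(grid)


def daily_budget(
    mask: np.ndarray,
    curve: HypsographicCurve,
    grid: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """Fraction of lake volume and bed area covered by a habitat mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != np.asarray(grid).size:
        raise ValueError("mask and depth grid have different lengths")
    vols, beds = weights if weights is not None else cell_weights(curve, grid)
    return (
        float(vols[mask].sum() / vols.sum()),
        float(beds[mask].sum() / beds.sum()),
    )


def classify_constraint(
    optimal_bed_frac: float,
    low_gt: float = 0.50,
    moderate_gt: float = 0.10,
    severe_lt: float = 0.01,
) -> str:
    """Constraint category for a day from its optimal bed-area fraction.

    Boundary values land downward: exactly 50 % is moderate, exactly 10 % and
    exactly 1 % are high (the 1-10 % band is closed on both ends).
    """
    if not 0.0 <= optimal_bed_frac <= 1.0:
        raise ValueError("bed-area fraction must lie in [0, 1]")
    if optimal_bed_frac > low_gt:
        return "low"
    if optimal_bed_frac > moderate_gt:
        return "moderate"
    if optimal_bed_frac >= severe_lt:
        return "high"
    return "severe"


def compute_budgets(
    t_daily: GriddedField,
    do_daily: GriddedField,
    curve: HypsographicCurve,
    bounds: HabitatBounds = HabitatBounds(),
    exclude: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Per-day budget table for aligned daily temperature and DO fields.

    Columns: date, usable_vol_frac, usable_bed_frac, optimal_vol_frac,
    optimal_bed_frac, category, excluded.  ``exclude`` marks a date window
    (e.g. the two weeks around autumn turnover) that category-based summaries
    should skip; the budgets themselves are still computed.
    """
    if not t_daily.times.equals(do_daily.times):
        raise ValueError("temperature and DO fields are on different time grids")
    if t_daily.depths.shape != do_daily.depths.shape or np.any(
        t_daily.depths != do_daily.depths
    ):
        raise ValueError("temperature and DO fields are on different depth grids")
    grid = t_daily.depths
    weights = cell_weights(curve, grid)
    rows = []
    for j, day in enumerate(t_daily.times):
        tcol = t_daily.values[:, j]
        docol = do_daily.values[:, j]
        u_vol, u_bed = daily_budget(
            habitat_mask(tcol, docol, bounds, "usable"), curve, grid, weights
        )
        o_vol, o_bed = daily_budget(
            habitat_mask(tcol, docol, bounds, "optimal"), curve, grid, weights
        )
        rows.append((day, u_vol, u_bed, o_vol, o_bed, classify_constraint(o_bed)))
    df = pd.DataFrame(
        rows,
        columns=[
            "date",
            "usable_vol_frac",
            "usable_bed_frac",
            "optimal_vol_frac",
            "optimal_bed_frac",
            "category",
        ],
    )
    df["excluded"] = False
    if exclude is not None:
        a, b = (pd.Timestamp(x) for x in exclude)
        df.loc[(df["date"] >= a) & (df["date"] <= b), "excluded"] = True
    return df


@dataclass(frozen=True)
class AnnualSummary:
    """One year of habitat history condensed to its extremes.

    ``both_suboptimal_frac_at_max_constraint`` uses the signed convention:
    positive = the optimal volume fraction remaining on the worst day;
    negative = the whole lake failed at least one optimal criterion that day,
    and the magnitude is the volume fraction failing *both* (too warm and too
    low in DO).  ``both_unusable_frac_at_max_constraint`` is the same for the
    usable tier.
    """

    year: int
    days_absent_optimal: int
    days_absent_usable: int
    min_optimal_volume_frac: float
    min_usable_volume_frac: float
    both_suboptimal_frac_at_max_constraint: float
    both_unusable_frac_at_max_constraint: float


def annual_summary(
    budgets: pd.DataFrame,
    t_daily: GriddedField,
    do_daily: GriddedField,
    curve: HypsographicCurve,
    bounds: HabitatBounds = HabitatBounds(),
    max_gap_days: int = 1,
    zero_tol: float = 0.0,
) -> AnnualSummary:
    """Summarise a contiguous daily budget series (nominally one year)."""
    if len(budgets) == 0:
        raise ValueError("empty budget series")
    dates = pd.DatetimeIndex(budgets["date"])
    gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if gaps.size and gaps.max() > max_gap_days:
        raise ValueError(f"budget series has a {gaps.max()}-day gap")

    def signed(tier: str) -> float:
        vol = budgets[f"{tier}_vol_frac"].to_numpy()
        j = int(np.argmin(vol))
        if vol[j] > zero_tol:
            return float(vol[j])
        day = dates[j]
        tcol = t_daily.column(day)
        docol = do_daily.column(day)
        both_bad = (tcol > bounds.temp_limit(tier)) & (
            docol < bounds.do_limit(tier)
        )
        vols = curve.cell_volumes(t_daily.depths)
        return -float(vols[both_bad].sum() / vols.sum())

    return AnnualSummary(
        year=int(dates[0].year),
        days_absent_optimal=int((budgets["optimal_vol_frac"] <= zero_tol).sum()),
        days_absent_usable=int((budgets["usable_vol_frac"] <= zero_tol).sum()),
        min_optimal_volume_frac=float(budgets["optimal_vol_frac"].min()),
        min_usable_volume_frac=float(budgets["usable_vol_frac"].min()),
        both_suboptimal_frac_at_max_constraint=signed("optimal"),
        both_unusable_frac_at_max_constraint=signed("usable"),
    )


def write_budget_csv(budgets: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "date",
        "usable_vol_frac",
        "usable_bed_frac",
        "optimal_vol_frac",
        "optimal_bed_frac",
        "category",
    ]
    budgets[cols].to_csv(path, index=False)
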