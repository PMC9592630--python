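"""Seeded synthetic lake and fish-telemetry generator.

The field data this pipeline was designed around (a small dimictic two-basin
lake with summer hypolimnetic oxygen depletion, and five depth-tagged fish)
are not public, so this module generates stand-ins with the statistical
structure the analysis assumes:

* **Temperature** — a seasonal surface sinusoid over a sigmoid thermocline
  that deepens through summer; after autumn turnover the column mixes and
  cools, staying cold under ice.  A zero-mean diel cycle rides on top of the
  hourly field, so daily means recover the base profile exactly.
* **Dissolved oxygen** — parameterised by a *constraint schedule*: each phase
  prescribes the fraction of lake-bed area that is optimal habitat, and the
  4 mg/L oxycline depth is found by inverting the hypsographic curve so the
  prescribed fraction is met exactly.  An ``absent`` phase pins the oxycline
  a safety margin above the 10 deg C isotherm, eliminating optimal habitat
  for exactly the configured days.  This makes configured habitat histories
  (absence windows, category calendars) recoverable ground truth rather than
  emergent quantities.
* **Fish** — a biased random walk in depth attracted to the coolest
  acceptable stratum (optionally a continuous foray oscillation through a
  depth band), emitting depth-coded pings at uniform random 60-180-s
  intervals with Gaussian sensor error quantised to the transmitter's
  resolution, plus a bounded 2-D walk for positions with a positioning-error
  score (HPE) calibrated so a configurable fraction exceeds the usual
  quality threshold.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from statistics import NormalDist

import numpy as np
import pandas as pd
import yaml

from .habitat_budget import classify_constraint
from .hypsometry import HypsographicCurve, lake658_like_hypsography
from .limnofield import DISSOLVED_OXYGEN, TEMPERATURE, GriddedField, default_depth_grid

__all__ = [
    "PhaseSpec",
    "LakeScenario",
    "FishScenario",
    "SimulatedFields",
    "default_study_phases",
    "simulate_fields",
    "simulate_fish",
    "write_scenario",
]


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of the habitat-constraint schedule.

    ``frac_start``/``frac_end`` prescribe the optimal bed-area fraction at
    the phase's first and last day (linear in between).  ``absent`` phases
    ignore the fractions and remove optimal habitat entirely.  ``mixed``
    phases have an unstratified (isothermal, cool) water column.
    """

    name: str
    n_days: int
    frac_start: float = 0.0
    frac_end: float = 0.0
    absent: bool = False
    mixed: bool = False


def default_study_phases() -> list[PhaseSpec]:
    """The study-year chronology: moderate spring, high mid-summer, severe
    early fall with a 29-day total loss of optimal habitat, a two-week
    turnover transition, and a long low-constraint winter."""
    return [
        PhaseSpec("moderate", 49, 0.45, 0.12),
        PhaseSpec("high", 65, 0.095, 0.015),
        PhaseSpec("severe", 9, 0.009, 0.006),
        PhaseSpec("absent", 29, absent=True),
        PhaseSpec("severe_tail", 1, 0.006, 0.006),
        PhaseSpec("turnover", 14, 0.05, 0.48, mixed=True),
        PhaseSpec("low", 199, 0.55, 0.70, mixed=True),
    ]


@dataclass
class LakeScenario:
    """Parameters of the synthetic lake's season.

    Temperatures in deg C, depths in metres, DO in mg/L.  The defaults
    emulate the monitored year of a small boreal two-basin lake: maximum
    surface temperature near 27 deg C in late July, a thermocline deepening
    from 2.0 to 4.5 m over the stratified season, a 5 deg C hypolimnion,
    well-oxygenated surface water over a hypoxic bottom layer all year, and
    turnover in early October.
    """

    start_date: str = "2015-05-09"
    phases: list[PhaseSpec] = field(default_factory=default_study_phases)
    # temperature season
    surface_temp_min: float = 0.8
    surface_temp_max: float = 26.5
    peak_doy: int = 208
    hypolimnion_temp: float = 5.0
    metalimnion_width_m: float = 1.2
    thermocline_start_m: float = 2.0
    thermocline_end_m: float = 4.5
    mixed_temp_cap: float = 9.0
    diel_amplitude: float = 0.5
    diel_decay_m: float = 1.5
    # dissolved oxygen profile shape
    do_surface: float = 9.2
    do_ramp_m: float = 1.0  # thickness of the surface->4 mg/L transition
    usable_sep_m: float = 0.8  # depth of the 2 mg/L oxycline below the 4 mg/L one
    anoxia_ramp_m: float = 1.3  # 2 mg/L -> 0 over this thickness
    absence_margin_m: float = 0.35  # oxycline pinned this far above the isotherm
    # grids
    max_grid_depth_m: float = 13.0
    dz: float = 0.1
    seed: int = 0

    @property
    def n_days(self) -> int:
        return sum(p.n_days for p in self.phases)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LakeScenario":
        raw = yaml.safe_load(Path(path).read_text())
        phases = raw.pop("phases", None)
        allowed = {f.name for f in dataclasses.fields(cls)} - {"phases"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        sc = cls(**raw)
        if phases is not None:
            sc.phases = [PhaseSpec(**p) for p in phases]
        return sc


@dataclass
class FishScenario:
    """Parameters of the simulated tagged fish.

    Fish hold near the coolest acceptable stratum, but on high-constraint
    days they forage in repeated vertical forays (``foray_rate_per_day``
    down-and-up traverses from below the isotherm into the hypoxic layer).
    Setting ``foray_band`` forces the continuous foray oscillation through a
    fixed (top, bottom) band for the whole span instead.
    """

    n_fish: int = 5
    total_lengths_mm: tuple[float, ...] = (570.0, 577.0, 584.0, 591.0, 598.0)
    cutoff_date: str = "2015-05-23"
    emission_interval_s: tuple[int, int] = (60, 180)
    depth_error_sd_m: float = 0.1
    depth_resolution_m: float = 0.08
    depth_max_m: float = 17.0
    hold_sd_m: float = 0.1
    hold_pull: float = 0.2
    comfort_offset_m: float = 0.7  # preferred depth below the 10 degC isotherm
    winter_depth_range_m: tuple[float, float] = (3.5, 10.0)
    foray_band: tuple[float, float] | None = None
    foray_rate_per_day: float = 93.0
    # positions
    lake_center: tuple[float, float] = (49.70, -93.73)
    basin_offset_m: float = 120.0  # centres of the two basin ellipses
    basin_radii_m: tuple[float, float] = (140.0, 90.0)
    horizontal_step_sd_m: float = 12.0
    position_error_sd_m: float = 3.0
    hpe_gt20_frac: float = 0.04
    duplicate_frac: float = 0.0
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FishScenario":
        raw = yaml.safe_load(Path(path).read_text())
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        for key in ("total_lengths_mm", "emission_interval_s", "winter_depth_range_m",
                    "foray_band", "lake_center", "basin_radii_m"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedFields:
    """Bundle returned by :func:`simulate_fields`.

    ``truth`` holds the designed daily ground truth: isocline/oxycline
    depths, the prescribed optimal bed fraction, its constraint category
    (from closed-form areas on the hypsographic curve, independent of the
    gridded-mask pipeline), and the optimal-absence flag.
    """

    scenario: LakeScenario
    curve: HypsographicCurve
    t_hourly: GriddedField
    do_daily: GriddedField
    truth: pd.DataFrame

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.truth["date"])


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------


def _surface_temp(scenario: LakeScenario, doy: np.ndarray) -> np.ndarray:
    mid = 0.5 * (scenario.surface_temp_max + scenario.surface_temp_min)
    amp = 0.5 * (scenario.surface_temp_max - scenario.surface_temp_min)
    return mid + amp * np.cos(2.0 * np.pi * (doy - scenario.peak_doy) / 365.25)


def _solve_band_bottom(
    curve: HypsographicCurve, z_top: float, target_bed_frac: float, z_max: float
) -> float:
    """Deepest extent z so that bed_area_between(z_top, z) hits the target."""
    target = target_bed_frac * curve.total_bed_area()
    if curve.bed_area_between(z_top, z_max) < target:
        raise ValueError(
            f"bed fraction {target_bed_frac:.3f} below {z_top:.2f} m is infeasible"
        )
    lo, hi = z_top, z_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if curve.bed_area_between(z_top, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_fields(
    scenario: LakeScenario, curve: HypsographicCurve | None = None
) -> SimulatedFields:
    """Generate the hourly temperature field, daily DO field, and ground truth."""
    if curve is None:
        curve = lake658_like_hypsography()
    grid = default_depth_grid(scenario.max_grid_depth_m, scenario.dz)
    dates = pd.date_range(scenario.start_date, periods=scenario.n_days, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    ts = _surface_temp(scenario, doy)
    th = scenario.hypolimnion_temp
    w = scenario.metalimnion_width_m

    phase_idx = np.repeat(np.arange(len(scenario.phases)), [p.n_days for p in scenario.phases])
    mixed = np.array([scenario.phases[i].mixed for i in phase_idx])
    absent = np.array([scenario.phases[i].absent for i in phase_idx])

    # fraction of the stratified season elapsed, for thermocline deepening
    strat_days = np.flatnonzero(~mixed)
    z_th = np.full(scenario.n_days, scenario.thermocline_end_m)
    if strat_days.size:
        prog = np.linspace(0.0, 1.0, strat_days.size)
        z_th[strat_days] = (
            scenario.thermocline_start_m
            + (scenario.thermocline_end_m - scenario.thermocline_start_m) * prog
        )

    # daily base temperature profiles and closed-form isocline depths
    t_base = np.empty((grid.size, scenario.n_days))
    z10 = np.zeros(scenario.n_days)
    z14 = np.zeros(scenario.n_days)
    mix_t = np.minimum(scenario.mixed_temp_cap, np.maximum(ts, scenario.surface_temp_min))
    for d in range(scenario.n_days):
        if mixed[d]:
            t_base[:, d] = mix_t[d]
            continue
        t_base[:, d] = th + (ts[d] - th) / (1.0 + np.exp((grid - z_th[d]) / w))
        for thr, out in ((10.0, z10), (14.0, z14)):
            if ts[d] > thr:
                arg = (ts[d] - th) / (thr - th) - 1.0
                if arg > 0:
                    out[d] = max(0.0, z_th[d] + w * np.log(arg))

    # oxycline schedule: prescribed optimal bed fraction, inverted exactly
    frac = np.zeros(scenario.n_days)
    for i, p in enumerate(scenario.phases):
        sel = phase_idx == i
        n = sel.sum()
        frac[sel] = np.linspace(p.frac_start, p.frac_end, n) if n > 1 else p.frac_start
    z4 = np.empty(scenario.n_days)
    z_cap = scenario.max_grid_depth_m - 0.2
    for d in range(scenario.n_days):
        if absent[d]:
            z4[d] = max(0.5, z10[d] - scenario.absence_margin_m)
        else:
            z4[d] = _solve_band_bottom(curve, z10[d], frac[d], z_cap)
    z2 = z4 + scenario.usable_sep_m

    do_vals = np.empty((grid.size, scenario.n_days))
    for d in range(scenario.n_days):
        xs = [0.0, max(0.01, z4[d] - scenario.do_ramp_m), z4[d], z2[d], z2[d] + scenario.anoxia_ramp_m]
        ys = [scenario.do_surface, scenario.do_surface, 4.0, 2.0, 0.0]
        xs, ys = zip(*sorted(set(zip(xs, ys))))
        do_vals[:, d] = np.interp(grid, xs, ys)

    # hourly temperature: base + zero-mean diel cycle (daily mean == base)
    hours = pd.date_range(dates[0], periods=scenario.n_days * 24, freq="h")
    h = np.arange(24)
    diel_t = np.cos(2.0 * np.pi * (h - 15) / 24.0)  # warmest mid-afternoon
    diel_z = scenario.diel_amplitude * np.exp(-grid / scenario.diel_decay_m)
    t_hour = (
        np.repeat(t_base, 24, axis=1)
        + diel_z[:, None] * np.tile(diel_t, scenario.n_days)[None, :]
    )

    truth = pd.DataFrame(
        {
            "date": dates,
            "surface_temp": np.where(mixed, mix_t, ts),
            "z14": z14,
            "z10": z10,
            "z4": z4,
            "z2": z2,
            "optimal_bed_frac": np.where(absent, 0.0, frac),
            "category": [
                classify_constraint(0.0 if a else f) for a, f in zip(absent, frac)
            ],
            "optimal_absent": absent,
            "mixed": mixed,
            "phase": [scenario.phases[i].name for i in phase_idx],
        }
    )
    return SimulatedFields(
        scenario=scenario,
        curve=curve,
        t_hourly=GriddedField(TEMPERATURE, grid, hours, t_hour),
        do_daily=GriddedField(DISSOLVED_OXYGEN, grid, dates, do_vals),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fish
# ---------------------------------------------------------------------------


def _foray_wave(phase: np.ndarray, dwell_frac: float = 0.25) -> np.ndarray:
    """One foray cycle in [0, 1]: descend, dwell at the bottom, ascend, dwell
    at the top.  The dwells let a 60-180-s emission schedule sample both
    extremes of every cycle (dwell time exceeds the longest gap at the
    default rate), so summed depth changes telescope to the full band width."""
    frac = np.mod(phase, 1.0)
    move = (1.0 - 2.0 * dwell_frac) / 2.0  # duration of each monotone leg
    out = np.ones_like(frac)
    down = frac < move
    out[down] = frac[down] / move
    up = (frac >= move + dwell_frac) & (frac < 1.0 - dwell_frac)
    out[up] = 1.0 - (frac[up] - move - dwell_frac) / move
    out[frac >= 1.0 - dwell_frac] = 0.0
    return out


def _inside_lake(fish: FishScenario, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b = fish.basin_radii_m
    dx = fish.basin_offset_m
    west = ((x + dx) / a) ** 2 + (y / b) ** 2 <= 1.0
    east = ((x - dx) / (0.8 * a)) ** 2 + (y / (0.85 * b)) ** 2 <= 1.0
    return west | east


def simulate_fish(
    fields: SimulatedFields, fish: FishScenario
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate tagged fish through the lake's season.

    Returns ``(detections, positions, meta)``: the depth-coded detection log
    (`timestamp, fish_id, depth_m`), the positioning-system log
    (`timestamp, fish_id, lat, lon, hpe`), and fish metadata
    (`fish_id, total_length_mm, cutoff_date`).
    """
    rng = np.random.default_rng(fish.seed)
    sc = fields.scenario
    start = pd.Timestamp(sc.start_date)
    span_s = sc.n_days * 86_400
    z10 = fields.truth["z10"].to_numpy()
    z2 = fields.truth["z2"].to_numpy()
    mixed = fields.truth["mixed"].to_numpy()
    zmax = fields.curve.max_depth
    # hold-mode fish switch to foraying on high-constraint days: repeated
    # traverses from just below the isotherm down through the hypoxic layer
    foray_day = (fields.truth["category"].to_numpy() == "high") & (
        fish.foray_rate_per_day > 0
    )
    band_top = np.minimum(z10 + 0.2, zmax - 2.0)
    # fish under high constraint stay within a ~3-m band at most
    band_bottom = np.minimum(np.minimum(z2 + 1.0, band_top + 3.0), zmax - 0.3)

    det_frames, pos_frames, meta_rows = [], [], []
    lat0, lon0 = fish.lake_center
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(lat0))
    sigma_h = 0.8
    mu_h = np.log(20.0) - sigma_h * NormalDist().inv_cdf(
        1.0 - min(max(fish.hpe_gt20_frac, 1e-6), 1 - 1e-6)
    )

    for k in range(fish.n_fish):
        fid = f"LW{6 + k}"
        length = fish.total_lengths_mm[k % len(fish.total_lengths_mm)]
        meta_rows.append((fid, length, fish.cutoff_date))

        lo, hi = fish.emission_interval_s
        n_guess = span_s // lo + 2
        gaps = rng.integers(lo, hi + 1, size=n_guess)
        t_s = np.cumsum(gaps)
        t_s = t_s[t_s < span_s]
        day_idx = (t_s // 86_400).astype(int)

        winter_depth = rng.uniform(*fish.winter_depth_range_m)
        target = np.where(
            mixed[day_idx] | (z10[day_idx] <= 0.0),
            winter_depth,
            np.minimum(z10[day_idx] + fish.comfort_offset_m, zmax - 1.0),
        )

        phase = fish.foray_rate_per_day * (t_s / 86_400.0) + rng.uniform()
        wave = _foray_wave(phase)
        if fish.foray_band is not None:
            top, bottom = fish.foray_band
            depth_true = top + (bottom - top) * wave
        else:
            depth_true = np.empty(t_s.size)
            z = target[0] if t_s.size else 0.0
            noise = rng.normal(0.0, fish.hold_sd_m, size=t_s.size)
            for i in range(t_s.size):
                d = day_idx[i]
                if foray_day[d]:
                    z = band_top[d] + (band_bottom[d] - band_top[d]) * wave[i]
                else:
                    z = z + fish.hold_pull * (target[i] - z) + noise[i]
                z = min(max(z, 0.1), zmax - 0.1)
                depth_true[i] = z

        depth_obs = depth_true + rng.normal(0.0, fish.depth_error_sd_m, size=t_s.size)
        depth_obs = np.round(depth_obs / fish.depth_resolution_m) * fish.depth_resolution_m
        depth_obs = np.clip(depth_obs, 0.0, fish.depth_max_m)

        stamps = start + pd.to_timedelta(t_s, unit="s")
        det = pd.DataFrame(
            {"timestamp": stamps, "fish_id": fid, "depth_m": np.round(depth_obs, 2)}
        )

        if fish.duplicate_frac > 0:
            # separate stream so injection never perturbs the base draws
            dup_rng = np.random.default_rng([fish.seed, k, 0xD0B])
            echo = dup_rng.random(len(det)) < fish.duplicate_frac
            dup = det[echo].copy()
            dup["timestamp"] = dup["timestamp"] + pd.to_timedelta(
                dup_rng.integers(1, 56, size=len(dup)), unit="s"
            )
            det = pd.concat([det, dup], ignore_index=True)
            det = det.sort_values("timestamp", kind="stable").reset_index(drop=True)
        det_frames.append(det)

        # bounded 2-D walk across the two basin ellipses
        x = np.empty(t_s.size)
        y = np.empty(t_s.size)
        cx, cy = -fish.basin_offset_m, 0.0
        steps = rng.normal(0.0, fish.horizontal_step_sd_m, size=(t_s.size, 2))
        for i in range(t_s.size):
            nx, ny = cx + steps[i, 0], cy + steps[i, 1]
            if not _inside_lake(fish, np.array([nx]), np.array([ny]))[0]:
                nx, ny = cx - steps[i, 0], cy - steps[i, 1]  # bounce back
                if not _inside_lake(fish, np.array([nx]), np.array([ny]))[0]:
                    nx, ny = cx, cy
            cx, cy = nx, ny
            x[i], y[i] = cx, cy
        x = x + rng.normal(0.0, fish.position_error_sd_m, size=t_s.size)
        y = y + rng.normal(0.0, fish.position_error_sd_m, size=t_s.size)
        hpe = np.exp(rng.normal(mu_h, sigma_h, size=t_s.size))
        pos_frames.append(
            pd.DataFrame(
                {
                    "timestamp": stamps,
                    "fish_id": fid,
                    "lat": np.round(lat0 + y / m_per_deg_lat, 7),
                    "lon": np.round(lon0 + x / m_per_deg_lon, 7),
                    "hpe": np.round(hpe, 2),
                }
            )
        )

    detections = (
        pd.concat(det_frames, ignore_index=True)
        .sort_values(["timestamp", "fish_id"], kind="stable")
        .reset_index(drop=True)
    )
    positions = (
        pd.concat(pos_frames, ignore_index=True)
        .sort_values(["timestamp", "fish_id"], kind="stable")
        .reset_index(drop=True)
    )
    meta = pd.DataFrame(meta_rows, columns=["fish_id", "total_length_mm", "cutoff_date"])
    meta["cutoff_date"] = pd.to_datetime(meta["cutoff_date"])
    return detections, positions, meta


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def write_scenario(
    fields: SimulatedFields,
    fish: FishScenario,
    outdir: str | Path,
    cast_interval_days: int = 14,
    cast_dz: float = 1.0,
) -> dict[str, Path]:
    """Write a scenario to the pipeline's CSV dialects.

    The DO field is emitted as sparse profile casts (every
    ``cast_interval_days`` days at ``cast_dz`` vertical steps), matching how
    oxygen is actually sampled; temperature is emitted as the hourly field of
    a logger string at fixed depths (0.5 m then 1-m steps).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["hypsography"] = outdir / "hypsography.csv"
    fields.curve.to_csv(paths["hypsography"])

    logger_depths = np.array([0.5] + list(np.arange(1.0, fields.curve.max_depth, 1.0)))
    zi = [fields.t_hourly.depth_index(z) for z in logger_depths]
    t = fields.t_hourly
    frame = pd.DataFrame(
        {
            "timestamp": np.repeat(t.times.values, len(zi)),
            "depth_m": np.tile(logger_depths, t.times.size),
            "value": t.values[zi, :].T.ravel().round(3),
        }
    )
    paths["temperature"] = outdir / "temperature_hourly.csv"
    frame.to_csv(paths["temperature"], index=False)

    cast_depths = np.arange(0.0, fields.do_daily.depths[-1] + 1e-9, cast_dz)
    zj = [fields.do_daily.depth_index(z) for z in cast_depths]
    keep = np.arange(0, fields.do_daily.times.size, cast_interval_days)
    do = fields.do_daily
    frame = pd.DataFrame(
        {
            "timestamp": np.repeat(do.times.values[keep], len(zj)),
            "depth_m": np.tile(cast_depths, keep.size),
            "value": do.values[np.ix_(zj, keep)].T.ravel().round(3),
        }
    )
    paths["do"] = outdir / "do_casts.csv"
    frame.to_csv(paths["do"], index=False)

    detections, positions, meta = simulate_fish(fields, fish)
    paths["detections"] = outdir / "detections.csv"
    detections.to_csv(paths["detections"], index=False)
    paths["positions"] = outdir / "positions.csv"
    positions.to_csv(paths["positions"], index=False)
    paths["fish_meta"] = outdir / "fish_meta.csv"
    meta.to_csv(paths["fish_meta"], index=False)
    paths["truth"] = outdir / "truth.csv"
    fields.truth.to_csv(paths["truth"], index=False)
    return paths
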