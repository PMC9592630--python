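# Methods

This note records the models, conventions, and numerical choices behind
`oxytherm`, and what the synthetic data can and cannot say about real lakes.

## Hypsometry

A lake is represented by its hypsographic curve: tabulated depths (starting
at 0) and planar cross-sectional areas, linearly interpolated between nodes.
Volume between two depths is the exact integral of the piecewise-linear area
(trapezoids split at the query depths), so volume and bed-area integrals are
exactly additive over adjacent intervals.

"Lake-bottom area" has two readings, both implemented:

- **planar projection** (default): bed between z₁ and z₂ is the horizontal
  annulus A(z₁) − A(z₂); the residual flat bottom A(z_max) is assigned at
  the maximum depth. Total bed area equals surface area.
- **frustum (slope-corrected)**: each band contributes its sloped surface
  ∫ √((dA/dz)² + P(z)²) dz, with perimeter P(z) = 2D√(πA(z)) from a
  shoreline-development ratio D ≥ 1 (closed form per linear segment). Total
  bed area exceeds surface area, as it must for any non-vertical basin wall.

Degenerate conventions: an empty interval has zero bed area even at the
maximum depth; intervals reaching z_max include the terminal flat bottom.

### The shipped lake fixture

`lake658_like_hypsography()` builds a synthetic stand-in for a small
double-basin boreal lake whose published totals are 547 966 m³ of volume,
86 227 m² of bed, 8.4 ha of surface, and 13.3 m maximum depth (secondary
basin 11.3 m). Since the published bed area exceeds the surface area, the
fixture uses frustum mode, calibrating D by bisection (landing at D ≈ 1.07,
reasonable for an elongated two-basin outline); a second bisection sets the
shape weight so the volume matches exactly. The shape is a steep littoral
shelf (exponential, 2-m decay) over a steep-walled basin that keeps nearly
constant area until a plunge near the bottom.

That shelf-heavy shape is deliberate: it makes habitat confined below a
depth z\* lose proportionally more bed area than volume — the situation that
makes benthivores especially sensitive to oxythermal squeeze. Geometry
limits how far this can hold: for any lake, habitat below z\* can satisfy
bed ≤ volume fraction only while z_max − z\* exceeds the mean depth
(V/A₀ ≈ 6.5 m here), i.e. z\* ≲ 6.8 m, and comfortably only to ~5 m. The
fixture satisfies it on z\* ∈ [0, 5] m, which spans the constraint depths
the analyses encounter (isoclines at ~4.5–6.2 m); it is a property of this
fixture, not a law.

## Water-column fields

- Vertical interpolation: piecewise linear in depth onto a 0.1-m grid
  (0.0–13.0 m by default, configurable per lake), exact at sample depths,
  edge-hold (no extrapolation) outside the sampled range, with a flag.
- Temporal interpolation (DO): per-depth linear in time between cast dates;
  edge-hold beyond the first/last cast, flagged. This mirrors carrying a
  single winter cast across the ice season on the assumption that DO does
  not recover under ice.
- Daily means (temperature): arithmetic mean of the hours present per local
  calendar day (midnight-to-midnight, naive local time throughout); days
  with fewer than 24 hours are averaged over what exists and flagged.

**Isoclines.** The isotherm is the *deepest* depth at which temperature
exceeds the threshold, linearly refined between grid cells; absent crossings
report 0 m (no warm exclusion) or the bottom depth (whole column warm). The
oxycline is the *shallowest* depth below the threshold; a fully oxygenated
column reports one grid step below the bottom.

**Habitat masks.** A cell is habitat iff it lies strictly below the deepest
supra-threshold temperature cell AND its DO exceeds the tier's floor.
Monotonic profiles are not assumed: the top-down temperature rule makes
inversions well-defined (a warm lens excludes everything above it), while
the DO rule is cellwise (a mid-column hypoxic lens excludes only itself,
since hypoxia normally pools at the bottom). Because 10 < 14 °C and
4 > 2 mg L⁻¹, the optimal mask is nested in the usable mask for any input —
a property the tests verify on random profiles.

## Budgets, categories, summaries

Masks are integrated as half-open 0.1-m cells; the last cell extends to the
true maximum depth so the cells partition the lake and an all-true mask
gives exactly 100 %. Category boundaries land downward: exactly 50 % is
moderate, exactly 10 % and 1 % are high (the 1–10 % band is closed on both
ends); thresholds are arguments, not constants. The two-week autumn-turnover
window is an exclusion *mask* on category-based summaries, passed as dates,
never hard-coded. Budgets come from a single profile station; multi-station
averaging is out of scope (between-basin differences in the motivating
system are ~5 %).

The annual summary counts zero-habitat days from the volume fraction, takes
minima over the series, and reports the day of maximum constraint with a
signed convention: if any habitat remains, the (positive) remaining volume
fraction; if none, minus the volume fraction failing both criteria at once.
The tie-break for "worst day" is the first day achieving the minimum.

## Telemetry

Filter order is unknown-ID → pre-cutoff → depth > 14 m → dedupe; the first
three commute, dedupe (which depends on what survives) is canonically last.
Dedupe keeps a detection only if it is ≥ 60 s after the *last kept*
detection of the same fish, thinning the stream to at least that spacing;
this makes filtering idempotent. HPE > 20 is reported but never filtered.
Annotation uses nearest-cell lookup (fields are already gridded): hourly
temperature at the detection hour, daily DO at the detection date; an
optional daily-temperature annotation supports the combined oxythermal
accounting at the DO field's resolution.

Occupancy tables classify with "inside" = T ≤ ceiling and DO ≥ floor, and
the violation columns as strict exceedances, so
inside + warm + lowDO − both = 100 % is an exact identity (threshold-equal
values are a measure-zero choice that the identity does not depend on). The
two suboptimal columns may overlap; the overlap is always reported.

Movement: vertical and lateral metrics come from separate streams (depth
pings vs positioning-system fixes), as the two are resolved independently.
Pairs straddling local midnight belong to neither day — the source analyses
sum "per day" without stating a rule, so this is a documented choice here.
Daily swim speed is the mean of per-pair speeds, not total distance over
total time; the two differ when detection gaps vary, and the per-pair mean
matches how speed is defined (per detection pair, then daily means).
Haversine distances use a 6 371 000 m sphere. All summed distances are
lower bounds on the path travelled (each leg is a straight line), so
subsampling can only decrease them — a tested invariant.

## Synthetic lake

**Temperature** is a seasonal surface sinusoid (0.8–26.5 °C, peak at
day-of-year 208) over a logistic (sigmoid) thermocline with 1.2-m
metalimnion width and a 5 °C hypolimnion; the thermocline deepens linearly
from 2.0 to 4.5 m across the stratified season. Isotherm depths then have
closed forms, which the generator records as ground truth. Mixed
(post-turnover / under-ice) days are isothermal, capped at 9 °C so winter
never re-imposes a warm exclusion. An exactly zero-mean diel cycle
(amplitude 0.5 °C at the surface, 1.5-m e-folding) rides on the hourly
field, so daily means recover the base profile to machine precision.

**Dissolved oxygen** is driven by a *constraint schedule* rather than a
depletion rate: each phase prescribes the optimal bed-area fraction on its
first and last day (linear in between), and the 4 mg L⁻¹ oxycline depth is
obtained by inverting the hypsographic curve (bisection) so the prescribed
fraction holds exactly; the 2 mg L⁻¹ oxycline sits 0.8 m deeper, with the
profile piecewise linear through (surface, 9.2) → (z₄, 4) → (z₂, 2) → 0.
`absent` phases instead pin the 4 mg L⁻¹ oxycline 0.35 m above the 10 °C
isotherm. This parameterisation makes the configured habitat history —
absence windows, the category calendar — exact ground truth that the
pipeline must recover, which is the basis of the round-trip tests. A
constant schedule yields a time-constant DO field (the no-depletion limit).

Two resolvability constraints follow from the 0.1-m grid and are part of
the schedule design: prescribed non-absent fractions should stay ≥ ~0.6 %
of bed area (thinner optimal bands than ~0.3 m cannot be resolved and would
read as absent), and schedules should not sit within ~0.5 percentage points
of a category boundary (grid discretisation moves computed fractions by up
to ~0.25 points). The default study-year schedule: moderate 49 d
(45→12 %), high 65 d (9.5→1.5 %), severe 9 d, absent 29 d, severe 1 d,
turnover ramp 14 d (mixed), low 199 d (55→70 %, mixed) — 366 days.

**Fish** hold near a target depth (0.7 m below the 10 °C isotherm, or an
individual winter depth drawn from 3.5–10 m when unstratified) via a
mean-reverting walk (pull 0.2, step s.d. 0.1 m per emission). On
high-constraint days they switch to foray mode: repeated traverses between
just below the isotherm and just below the 2 mg L⁻¹ oxycline (capped at a
3-m band), at 93 cycles day⁻¹. Each foray cycle is descend → dwell →
ascend → dwell with 25 % dwells; at the default rate the dwell (232 s)
exceeds the longest emission gap (180 s), so sampled depth changes
telescope to the full band width and the foray rate is recoverable from
daily vertical totals. Emissions are Uniform(60, 180) s (integer seconds);
reported depth adds Gaussian error (s.d. 0.1 m) quantised to the 0.08-m
transmitter resolution and clipped to the 17-m sensor range. Positions are
a bounded 2-D walk over two overlapping basin ellipses with 3-m positioning
error; HPE scores are lognormal with the location parameter set so a
configured fraction (4 % by default) exceeds 20. An optional echo-injection
mode duplicates detections at +1–55 s to emulate receiver overlap; the
dedupe filter must remove exactly these. All draws come from one seeded
generator per scenario (echo injection uses a derived, independent stream so
the base track is invariant to it); identical seeds give byte-identical CSVs.

**What the generator does not emulate.** No heat or oxygen budget is solved:
the fields are geometric constructions matching the *shape* of a monitored
season, not process dynamics. Profiles are noise-free and perfectly
monotone; real casts have sensor noise, internal waves, and metalimnetic
oxygen minima. Fish behaviour is a two-state caricature tuned to reproduce
qualitative occupancy patterns (narrow thermal band, hypoxia use under
constraint, high-constraint foraying), not a fitted movement model; lateral
movement is constraint-independent by construction. Passing round-trip
tests therefore demonstrates that the *pipeline arithmetic* is faithful —
not that the pipeline is robust to real-world profile pathologies, clock
drift, or detection dropout.

## Problem sizes and determinism

The test suite simulates one full 366-day year (fields only, ~1 s), short
multi-day fish scenarios, and an 8-day foray-recovery scenario; the
acceptance script uses the same sizes and finishes in a few seconds. Random
inputs in tests use fixed seeds (hypothesis profiles are seeded by pytest's
derandomisation defaults); the acceptance script threads its `--seed`
through every stochastic component.

## Known limitations

- Frustum bed areas depend on an assumed depth-independent shoreline
  development D; real lakes vary D with depth.
- The top-down temperature rule and cellwise DO rule are asymmetric by
  design; a bottom-up DO variant (for lakes with surface hypoxia) is not
  implemented.
- Edge-hold temporal interpolation means pre-first-cast and post-last-cast
  DO are constant, which can understate spring reoxygenation if casts start
  late.
- The foray estimator assumes all vertical travel occurs within the stated
  band; movement outside it inflates the count.
- `annual_summary` takes the daily temperature and DO fields (not the masks)
  so it can evaluate the both-criteria-failing overlap directly.
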