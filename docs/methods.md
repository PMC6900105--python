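# Methods

## The minimal-flight-time model

A desert crossing is modelled as motion through a 3D lattice of
candidate flight positions: latitude/longitude on a regular 0.4° grid
clipped to a migration-corridor polygon, and altitude as one of up to 16
pressure layers (1000, 975, …, 550, 500 mb — ground to roughly 5.5 km).
A move connects a node to each of its 8 horizontal lattice neighbours at
the same layer or one layer up or down.  Purely vertical moves are
excluded: a zero-length edge would cost zero time, making altitude
changes free and their ordering along a path arbitrary.

The bird flies at a constant airspeed (default 18.05 m/s, a typical
flapping-flight airspeed for a medium-sized shorebird) and holds its
intended track by drift compensation: with tailwind w∥ and crosswind w⊥
relative to the leg bearing, the along-track groundspeed is

    g = w∥ + sqrt(a² − w⊥²),

infeasible when |w⊥| ≥ a (the track cannot be held) or g ≤ 0 (no
forward progress).  The weight of an edge is the great-circle length of
the leg divided by g, with the wind sampled at the *origin* node.
Infeasible edges carry infinite weight rather than being deleted, so an
overconstrained graph degrades to an explicit "unreachable" result
instead of an error.

Wind at a node is matched in time by a straight-line estimate: departure
time plus the great-circle distance from the crossing's departure node
divided by airspeed, rounded to the nearest 6-hourly analysis
(0/6/12/18 UTC; exact midpoints go to the earlier analysis, as do ties
in nearest-neighbour spatial lookups).  Because the estimate depends
only on the departure node, every node's wind is fixed for a given
crossing, the graph has static weights, and plain Dijkstra is exact.
The alternative — re-matching wind at each expansion's tentative arrival
time — defines a time-expanded graph; the straight-line interpretation
was chosen because it keeps the search exact and cheap, and because the
time scale of a crossing (1–2 days) spans only a few analysis windows.

The search orders labels lexicographically by (total time, edge count,
node sequence).  Appending an edge preserves this order, so Dijkstra
with the composite key returns a unique, bit-stable optimal path: ties
in time break toward fewer edges, then toward the lexicographically
smallest node sequence.  The test suite holds the search to an
exhaustive branch-and-bound enumeration (admissible bound: remaining
great-circle distance at airspeed plus the field's maximum wind speed)
on a 50-grid random suite, tie-breaks included.

Two grid variants bracket the bird's knowledge.  The *uninformed* grid
is the full corridor: the time-optimal route given perfect knowledge of
the winds.  The *informed* grid keeps only nodes within a buffer
(default 0.5°, measured in planar degree space against the
piecewise-linear interpolation of the observed in-flight fixes; at 0.4°
lattice scale inside |lat| ≤ 40° the difference from the true central
angle is far below one cell) — all pressure layers retained, since
Argos fixes carry no altitude.  The informed node set is a subset of
the uninformed one by construction, so the uninformed minimal time is
equal or shorter on every crossing; the gap measures how much the
time-minimisation assumption could overstate the bird's efficiency.

## Track ingestion and fate diagnosis

Input fix tables are assumed pre-filtered by a hybrid Argos filter; the
package applies only the quality-class retention rule (keep 3, 2, 1, 0,
A, B; drop Z), which is idempotent and order-preserving.  A crossing is
a maximal run of fixes inside a desert-mask polygon; the departure node
and time come from the last fix before entry snapped to the lattice (at
the lowest-altitude configured layer), the arrival node from the first
fix after exit.  An entry gap longer than 6 h (a duty-cycle artefact)
flags the departure snap as low-confidence.  Season is the sign of the
net latitude change.  For birds that died mid-desert the intended
arrival node is unobservable; the arrival node of the individual's most
recent prior completed northward crossing stands in (site fidelity on
the staging grounds), and crossings with no such prior are excluded
with a logged reason.

Fate rules, evaluated on transmitter behaviour after the event:

* **Activity constant** (9.5 g tags): sample variance of the activity
  channel over a 7-day window below 10⁻⁶ × the tag's lifetime variance.
* **Temperature diurnal** (5 g tags): amplitude of the 24-h harmonic
  (least-squares fit of sin/cos at one cycle per day) exceeding 3 × the
  residual SD over a 7-day window.  A living bird buffers its tag's
  temperature; a carcass tracks the day–night cycle.
* **Ceased transmitting**: the transmitter stops within the crossing
  and no fix arrives within 365 days.

The two thresholds (10⁻⁶ and 3) are package choices — the diagnostic
descriptions they implement are qualitative.  For an uncompleted
crossing the sensor rules are evaluated on the *trailing stationary
segment* of the transmissions (the suffix of fixes within 0.2° of the
final position, if it spans ≥ 2 days): a dead bird's transmitter keeps
duty-cycling from the carcass, so the diagnostic window is the tail of
the record, not a "post-crossing" segment that never exists.  The
window uses its last 7 days, clear of the transient around the death
event.  For a completed crossing the rules are evaluated on the 14 days
after arrival — later records belong to later crossings.  A subsequent
resighting overrides any fired rule (the transmitter failed, the bird
did not) with a logged warning.

The relative departure date of a northward crossing is its departure
day-of-year minus the mean northward departure day-of-year over the
reference window (all northward crossings supplied).

## Statistical models

All mixed models carry an individual random intercept for the
non-independence of repeat crossings by the same bird, and all are
fitted by maximum likelihood (not REML) so likelihood-ratio statistics
between nested fits are well defined.

* Seasonal contrast: Gaussian LMM, flight_time ~ season +
  (1 | individual), via statsmodels MixedLM.
* Mortality: binomial GLMM, died ~ flight_time + relative_departure +
  tag_type + (1 | individual).  statsmodels offers no ML binomial mixed
  model with a marginal likelihood, so the fit is implemented directly:
  the random intercept is integrated out with 15-node Gauss–Hermite
  quadrature and the marginal log-likelihood maximised by L-BFGS-B over
  (β, log σᵤ), with box bounds (|β| ≤ 60, log σᵤ ∈ [−6, 3]) keeping the
  search out of overflow regions.  Standard errors come from the
  numerical Hessian.  The implementation agrees with lme4::glmer
  (adaptive GH, nAGQ = 15) to ~3 decimal places on test fixtures, which
  the suite checks through Rscript.  A constant tag-type column is
  dropped and reported; slopes are reported both raw and standardized
  (per SD of the covariate), since the natural scale of the flight-time
  effect is ambiguous.  Suspected complete separation (|β| > 20) is
  flagged, not hidden; a boundary random-intercept variance (0) is
  reported as such.
* Informed vs uninformed: Gaussian LMM of flight time on grid variant,
  plus the mean percentage shortening mean((inf − uninf)/inf) × 100.
  Any pair with uninformed > informed is an upstream invariant breach
  and raises.

Fixed effects are tested by parametric bootstrap likelihood-ratio
tests: simulate B response vectors from the fitted null, refit both
models to each, and report p = (1 + #{LRT* ≥ LRT}) / (B + 1).  Each
effect is tested by dropping it from the full model (one p per effect).
B defaults to 1000; bootstrap refits warm-start from the observed fit.
The type-I calibration check uses B = 19, for which "reject at
α = 0.05" reduces to "no bootstrap replicate reaches the observed LRT"
— an exact level-0.05 Monte-Carlo test — making a 200-dataset
calibration affordable.

## The synthetic-data generator

The generator emulates the study's data products with known ground
truth.  Winds: NE-trade mean flow (default u = v = −3.5 m/s, i.e.
blowing toward the southwest) scaled by a per-level shear profile
(1.0–1.6, strongest aloft) plus AR(1) noise (SD 2 m/s, lag-1
correlation 0.8 per 6-h step) shared across the grid as a
synoptic-scale anomaly.  A seasonal-reversal factor rescales the trade
means; −1 turns the trades around and flips the seasonal contrast
exactly.

Cohorts: each individual crosses a ~1800 km corridor (default
14.8–32.4°N, 3.2° of longitude, 4 pressure layers at 925/850/750/650 mb)
southward each autumn and northward each spring, along a great-circle
trajectory with smooth cross-track jitter (SD 0.15°), at the pressure
level with the best tailwind at departure, timed by integrating the
drift-compensated groundspeed through the sampled winds (floored at
4 m/s — a bird cannot hover).  Transmitters duty-cycle (8 h on/24 h
charge, or 10 h on/48 h charge for 30% of the 9.5 g tags; 7.5% of birds
carry 5 g temperature tags), producing ≈7 ± 2 usable in-flight fixes on
longer crossings and fewer on short, wind-assisted ones; some crossings
yield no in-flight fix at all and are invisible to segmentation, as in
real duty-cycled data.  Northward mortality follows
logit P(die) = −10 + 0.25 × realized flight time (h) — the *truth-side*
time actually flown, not the pipeline's estimate, so estimation error
is honestly present in recovery tests; with the default corridor this
yields ~35 h mean northward times and ~25–30% mortality.  Southward
crossings are safe, and a death ends the individual's record.  Dead
birds are assigned one generating rule (sensor rule with probability
0.7, else cessation): the carcass keeps transmitting with a frozen
activity value or a diurnal temperature signal for 18 days, or goes
silent immediately.

Two RNG streams (truth-level and fix-level) derive from the config
seed, so the truth table is identical whether or not the fix table is
generated.

What the generator does **not** emulate: Argos location-error ellipses
(scatter is isotropic Gaussian, SD 0.03°), stopover behaviour,
spatially structured winds (the noise is coherent across the grid, so
optimal routes rarely detour and the informed/uninformed gap is near
zero — the invariant and its limit behaviour are still fully
exercised), altitude-dependent airspeed, and temperature constraints on
flight.  Passing tests therefore demonstrate correctness of the
algorithms and estimators under these idealized conditions, not
field-data performance.

## Problem sizes and numerical choices

The synthetic studies run at desk scale by design: a 45 × 9 × 4-level
grid (~1600 nodes) rather than the full 16-layer continental corridor;
cohorts of 60–200 individuals over 1–4 study years (≈200–500
crossings); bootstrap sizes 19–199 depending on the role of the test.
The exhaustive-search oracle uses 4 × 4 × 2 grids, where enumeration
with an admissible bound is exact and fast.  All timestamps are UTC;
day-of-year is 1-based; lattice coordinates are rounded to 6 decimals
so node equality is exact; tolerances on closed-form route checks are
1e-9 relative.  Earth is a sphere of radius 6 371 000 m; rhumb-line
geometry was rejected as immaterial at 0.4° resolution.

## Known limitations

* The minimal flight time is a lower bound: real birds do not know
  future winds; the informed/uninformed gap only brackets this
  optimism.
* Wind-time matching by straight-line estimate ignores en-route detour
  time; on 1–2-day crossings this can shift a node's analysis window by
  at most one or two 6-h steps.
* Dead birds with no prior completed northward crossing are excluded
  from route simulation (their arrival node is unresolvable), which at
  desk scale removes a share of first-spring deaths from pipeline-level
  mortality summaries; parameter-recovery tests for the mortality model
  therefore run on the generator's truth table.
* The GLMM's quadrature assumes a single Gaussian random intercept;
  crossed or nested grouping structures are out of scope.
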