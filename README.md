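# windcross

Wind-optimal desert-crossing flight times and in-flight mortality
analysis for satellite-tracked migratory birds.

## The problem

Long-distance migrants that cross large barriers — the Sahara, open
ocean — cannot stop when conditions turn against them.  For birds
tracked with solar Argos transmitters (PTT-100 class), the duty cycle
yields only a handful of locations per crossing, so neither the route,
the altitude, nor the wind assistance actually experienced can be
observed directly.  What *can* be computed is the **minimal flight
time**: the duration of the time-optimal route through the wind field
the bird flew in, used as a lower-bound proxy for the wind-induced cost
of that crossing.  Paired with transmitter-based fate diagnosis, it lets
one ask whether crossings flown in worse winds kill more birds.

`windcross` implements that pipeline end to end:

1. **Wind fields** (`wind_model`) — reanalysis-style 4D grids
   (6-hourly analyses × pressure levels × lat × lon, u/v in m/s), read
   from NetCDF or synthesized as NE-trade fields with vertical shear and
   AR(1) day-to-day variability.
2. **Flight mechanics** (`kinematics`) — great-circle geodesy and
   drift-compensated groundspeed at constant airspeed *a* = 18.05 m/s:
   for tailwind *w*∥ and crosswind *w*⊥,
   `g = w∥ + sqrt(a² − w⊥²)`, infeasible when |*w*⊥| ≥ *a* or *g* ≤ 0.
3. **Route graph** (`route_graph`) — a 0.4° lattice of nodes over a
   migration-corridor polygon at up to 16 pressure layers
   (1000–500 mb); moves go to the 8 horizontal neighbours at the same
   layer or one layer up/down; edge weight = travel time under the wind
   at the origin node, matched to the nearest 6-hourly analysis of the
   node's straight-line arrival estimate.  Minimal flight time is an
   exact Dijkstra search with deterministic tie-breaking (fewer edges,
   then lexicographic node order).  An *informed* grid restricts nodes
   to a buffer around the observed in-flight fixes; the *uninformed*
   grid is the full corridor, so its minimal time is by definition equal
   or shorter.
4. **Track ingestion** (`tracks_io`) — Argos quality-class filtering
   (keep 3/2/1/0/A/B, drop Z), desert-crossing segmentation against a
   mask polygon, and fate diagnosis from three transmitter rules:
   a 9.5 g tag whose activity sensor goes constant, a 5 g tag whose
   temperature sensor turns diurnal (a carcass tracks ambient
   temperature), or a transmitter that stops mid-bout and never returns.
   A later resighting overrides any rule.
5. **Inference** (`stats`) — mixed models with an individual random
   intercept: a Gaussian LMM of minimal flight time on season; a
   binomial GLMM of northward mortality on flight time, relative
   departure date and transmitter type (marginal ML via Gauss–Hermite
   quadrature); an informed-vs-uninformed LMM.  Fixed effects are tested
   by parametric bootstrap likelihood-ratio tests.
6. **Synthetic data** (`synthetic_data`) — complete study stand-ins
   with known ground truth: trade-wind scenarios, jittered great-circle
   trajectories flown through the winds, duty-cycled sparse fixes
   (≈7 ± 2 per crossing), and mortality with
   `logit P(die) = −10 + 0.25 × flight time (h)` on northward crossings.

## Worked example

```python
import pandas as pd
from windcross import pipeline
from windcross.stats import fit_season_lmm
from windcross.synthetic_data import (
    CohortConfig, default_corridor, default_desert_mask,
    generate_cohort, generate_seasonal_scenario,
)

cfg = CohortConfig(n_individuals=20, n_years=1, seed=42)
fields = generate_seasonal_scenario(cfg)          # paired trade-wind fields
fixes, truth = generate_cohort(cfg, fields)       # duty-cycled Argos-style fixes

crossings = pipeline.extract_crossings(fixes, default_desert_mask())
flat = [f for per_year in fields.values() for f in per_year]
routes = pipeline.simulate_routes(crossings, flat, default_corridor())

print(routes[["crossing_id", "season", "fate",
              "time_uninformed", "time_informed"]].head())
rows = routes.rename(columns={"time_uninformed": "flight_time_h"})
fit = fit_season_lmm(rows[["flight_time_h", "season", "individual"]], B=199, seed=1)
print(f"season contrast (northward - southward): "
      f"{fit['season_northward']:.2f} h  "
      f"(bootstrap p = {fit.bootstrap_p['season_northward']:.3f})")
```

Output:

```
  crossing_id     season      fate  time_uninformed  time_informed
0   bird000-0  southward  survived        18.072528      18.072528
1   bird000-1  northward  survived        27.389522      27.389522
2   bird001-2  southward  survived        19.342934      19.357231
3   bird001-3  northward  survived        39.169134      39.308104
4   bird002-4  southward  survived        20.298977      20.298977

season contrast (northward - southward): 11.91 h  (bootstrap p = 0.005)
```

Southward crossings ride the NE trades and take ~19 h through this
synthetic corridor; northward crossings fight the same trades and take
~30–40 h.  The LMM contrast quantifies that difference with the
individual as a random intercept; its bootstrap p is the fraction of
null simulations with a likelihood ratio at least as large as observed.
`time_uninformed ≤ time_informed` holds row by row, because the
informed grid is a subset of the uninformed one.

A thin CLI wraps the same stages:

```sh
windcross synth --seed 1 --n-individuals 60 --out cohort/
windcross simulate --fixes cohort/fixes.csv --wind cohort/wind_southward_2016.nc \
    --wind cohort/wind_northward_2017.nc --out routes.csv
windcross analyze --routes routes.csv --bootstrap 999 --seed 42 --out fits.json
```

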