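# treeline-drivers

Driver attribution for alpine treeline expansion.  Given a DEM, coarse
monthly climate, and multi-year binary presence maps of a treeline
species, the package derives topographic and climatic factor rasters,
computes vegetation-change responses, and quantifies single-factor and
interactive driver influence with the stratified-heterogeneity *q*
statistic

    q = 1 − SSW/SST,   SSW = Σ_h N_h σ_h²,   SST = N σ²,

the fraction of the response's spatial variance explained by a factor's
strata.  The interaction detector evaluates q on the overlay of two
factors' strata and classifies each pair (independent, bivariate
enhancement, nonlinear enhancement, weakening).  It is written for
spatial ecologists studying treeline ecotones — where expansion is
driven by interacting terrain (elevation, slope, relief, topographic
wetness index TWI = ln(α/tanβ)) and climate (growing-season and
coldest/warmest-month precipitation and temperature) — but the detector
machinery applies to any gridded response.

A synthetic volcano-landscape generator (cone DEM, lapse-rate climate
with correlated anomalies, logistic colonization with known factor and
interaction effects) makes every stage testable end to end, including
whether planted drivers are recovered.  See `docs/methods.md` for the
model details and design choices.

## Layout

- `src/treeline_drivers/` — the library: `raster` (grid container +
  ASCII-grid I/O), `terrain` (slope/aspect/relief/D8/TWI), `climate`
  (MLR downscaling, seasonal factors, collinearity pruning), `cover`
  (spectral indices, sample handling, SVM presence mapping), `change`
  (change maps, rates, sector summaries, density response),
  `geodetector` (the q statistic), `synthetic` (the landscape
  generator), `experiments` (driver-recovery experiments), `pipeline` +
  `cli` (orchestration).
- `analysis/` — numbered narrative scripts reproducing the study flow
  on the synthetic scene; each writes its tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

## Worked example

```
$ python analysis/01_simulate_landscape.py
scene seed 1: elevation 1814-2670 m
presence area 3500 -> 4630 hm^2 (32.3% total increase over 19 years)

$ python analysis/05_recovery_experiments.py
dominant-factor experiment: 20/20 replicates rank the planted TWI driver first (median top q = 0.728)
interaction experiment: 20/20 replicates rank TWI x Pre_1 first as nonlinear enhancement (median top q_ab = 0.681)
```

The first script builds a 10×10 km synthetic scene whose presence maps
expand from 3500 to 4630 hm² across the 2002/2010/2017/2021 epochs
(≈ 1.7 %/a under the calendar-span convention).  The recovery scripts
then show that when a single dominant driver (TWI) or a single pairwise
interaction (TWI × coldest-month precipitation) is planted in the
colonization model, the detectors identify it in 20 of 20 replicates,
with median top q ≈ 0.7 — i.e. the planted driver explains about 70% of
the spatial variance of the per-attempt colonization frequency.

Scripts 02–04 exercise the intermediate stages: terrain + downscaling
(station RMSE 0.31 °C, R² 0.93 on the synthetic August field; 9
candidate factors pruned to 6 at |r| > 0.90), per-sector expansion
rates and maximum elevations, and the per-sector factor/interaction
rankings on the observational density response.

There is also a CLI over the same functions:

```
treeline-drivers simulate --seed 1 --out runs/scene
treeline-drivers terrain --dem runs/scene/dem.asc --out runs/terrain
treeline-drivers run --seed 1 --out runs/full      # full pipeline
```

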