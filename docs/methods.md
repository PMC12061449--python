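# Methods

This package attributes alpine treeline expansion to topographic and
climatic drivers using the stratified-heterogeneity *q* statistic.  The
pipeline has five computational stages — terrain derivatives, climate
downscaling and factor derivation, binary cover mapping, change metrics,
and the factor/interaction detectors — plus a synthetic-landscape
generator that makes the whole chain testable end to end with known
ground truth.

## The q statistic

For a response *Y* observed on *N* units partitioned into strata
*h = 1..L* by one explanatory factor,

    q = 1 − SSW / SST,    SSW = Σ_h N_h σ_h²,    SST = N σ²,

with **population** variances (σ² divides by *N*, σ_h² by *N_h*), so
that N_h σ_h² is exactly the within-stratum sum of squared deviations.
*q* is the fraction of the response's spatial variance explained by the
stratification: 0 when strata carry no information, 1 when the response
is constant within every stratum.  The interaction detector computes *q*
on the overlay of two factors (distinct label pairs) and classifies the
pair by comparing q(A∩B) with qA, qB and their sum:

| condition | category |
|---|---|
| q(A∩B) > qA + qB | nonlinear enhancement |
| q(A∩B) = qA + qB (within tol) | independent |
| q(A∩B) > max(qA, qB) | bivariate enhancement |
| min ≤ q(A∩B) < max | single-factor weakening |
| q(A∩B) < min(qA, qB) | nonlinear weakening |

Sum comparisons are evaluated before max comparisons; the tie tolerance
is 1e−9 absolute.  Because the overlay refines both partitions,
q(A∩B) ≥ max(qA, qB) holds *exactly* when all three values are computed
on the same observations — which this implementation enforces by
recomputing qA and qB on the retained overlay sample — so the weaken
categories are reachable only under unequal sample handling.  A factor
overlaid with itself gives q(A∩A) = qA; this boundary tie is classified
as bivariate enhancement.

Under the null (response independent of the strata) E[q] ≈ (L−1)/(N−1);
the test suite verifies this by Monte-Carlo.  No significance test is
attached to q (the noncentral-F test of the original method is a
documented extension point, not implemented).

Stratification defaults: quantile (equal-frequency) bins with k = 5
strata for continuous factors, configurable to equal-interval or
natural-breaks (a 1-D variance-minimising k-means partition, checked in
tests against an exhaustive dynamic-programming optimum); strata with
fewer than 2 observations are dropped and logged, never merged;
observations with any missing value are excluded listwise.  A built-in
sensitivity report sweeps k over 3..8.

## Terrain derivatives

Slope and aspect use the Horn third-order finite difference on the 3×3
neighbourhood, with one-sided differences at grid borders; aspect is the
azimuth of steepest descent (degrees clockwise from north) with a flat
sentinel (−1) below a 1e−6 m/m gradient threshold.  Relief is the
max − min elevation in a square window (default 3×3 cells, i.e. 150 m
at 50 m resolution; the window is a free parameter of the method).
Flow accumulation is single-direction D8 over a priority-flood
sink-filled surface; the fill raises pits to their pour point plus a
1e−6 m epsilon gradient so every cell keeps a strictly descending path,
which also resolves flats deterministically.  Steepest-descent ties
break in the fixed neighbour order E, SE, S, SW, W, NW, N, NE.  The
specific catchment area is α = (accumulated cells × cell area) / cell
width, and TWI = ln(α / max(tan β, 0.001)); the 0.001 floor keeps flat
cells finite.

Slope classes follow the seven-class geomorphological taxonomy applied
in degrees — plain [0,2), gentle ramp [2,5), ramp [5,15), steep [15,25),
very steep [25,35), scarp [35,55), vertical ≥ 55 — with the scarp class
extended through 55° so the classes are contiguous.  Aspect sectors
(northern/eastern/southern/western quadrants centred on the cardinal
directions) are assigned from the azimuth summit → cell centre; any
sector can be masked out of the analysis (the study-area configuration
masks the eastern sector).

## Climate downscaling and factors

Coarse monthly fields are downscaled by OLS on [elevation, slope,
sin(aspect), cos(aspect)] fitted over coarse cells and predicted at fine
cells; aspect enters as a sin/cos pair to respect its circularity, and a
rank-deficient design falls back to the elevation-only lapse regression
with a logged warning.  Validation reports RMSE and R² = 1 − SSE/SST at
station points.  Seasonal factors: Pre_g (growing-season precipitation
sum), Pre_1 (January = coldest-month precipitation), Pre_8 (August
precipitation), T_MEAN8 (August mean temperature), T_MEANg
(growing-season mean temperature).  The growing season defaults to
June–September, the NE-Asia alpine convention; coldest/warmest months
are fixed to January/August rather than computed per cell.  Candidate
factors are pruned greedily while any pair has |Pearson r| > 0.90,
dropping the lower-priority member of the worst pair (priority defaults
to the factor-table order: climate first, then topography).

## Cover mapping

The feature space is nine bands: six reflectances plus NDVI =
(NIR−Red)/(NIR+Red), NDWI = (Green−NIR)/(Green+NIR), and NDSI =
(SWIR1−NIR)/(SWIR1+NIR).  NDSI here is the *soil* index convention
(SWIR against NIR), matching the index's role of separating bare ground
from vegetation.  With multiple acquisition dates, per-band temporal
mean/SD layers can be appended.  Sample handling: boundary filtering
then visual screening (with a conserved count ledger), and a stratified
70/30 split whose training size rounds half-up (411 samples → 288).
The classifier is a pluggable fit/predict contract defaulting to a
standardised soft-margin RBF SVM (scikit-learn); the degenerate case of
identical feature vectors with mixed labels returns the majority-class
map with a warning.  Accuracy is overall percent correct at validation
points, reported to one decimal.  Manual patch-level interpretation is
not automated; a per-patch class-change report is emitted for human
review instead.

## Change metrics

Change maps classify each cell as stable-absent, stable-present,
expanded, or reduced.  The annual rate is the simple convention
((A₂−A₁)/A₁) × 100 / span; the span divisor is configurable between the
calendar difference and a stated span (the replication profile of the
source analysis pins a 20-year divisor for a 2002–2021 window, which
reproduces its arithmetic of 24.26% / 20 = 1.21 %/a even though the
calendar difference is 19).  Areas are reported in hm² (10⁴ m²).
Sector summaries give per-sector areas, rates, and maximum presence
elevations.  The density-increase response aggregates the expanded
indicator over blocks of fine cells (default 10×10, i.e. 500 m analysis
cells) as a percentage of valid fine cells; partial edge blocks use the
cells they contain.

## The synthetic landscape

The generator emulates the structure of a volcanic treeline study area:

- **DEM** — a cone (summit 2690 m, slope 0.12) centred on a 200×200-cell
  grid at 50 m, plus a Gaussian random field (amplitude 15 m,
  correlation length 5 cells).  The scene spans roughly 1800–2700 m, the
  elevation band of a high treeline ecotone.
- **Climate** — monthly sea-level normals for a continental NE-Asia
  climate, lapsed at −0.0065 °C/m, with a warm-south aspect modulation
  (0.5 °C) and *spatially correlated* anomaly fields (SD 0.3 °C / 3 mm,
  correlation length 8 cells).  Correlated anomalies matter: white cell
  noise averages away under block aggregation, which would leave
  January precipitation collinear with elevation at analysis scale and
  make driver attribution between them ill-posed.  Precipitation adds a
  +0.01 mm/m elevation gradient and is floored at 0.
- **Colonization** — presence starts below the 0.35 elevation quantile
  and spreads year by year: an absent cell with an occupied neighbour
  (Chebyshev radius 1) colonizes with probability
  scale × logistic(β₀ + Σβᵢzᵢ + Σβᵢⱼzᵢzⱼ) over z-scored factors;
  presence never reverts.  Defaults (β₀ = −1, scale = 0.6, β_elev =
  −0.5, β_TWI = β_Pre1 = 0.5, β_TWI×Pre1 = 1.0) give ≈ 30% total area
  growth over 19 years (≈ 1.7 %/a), comparable to observed treeline
  expansion rates.

What the generator does *not* emulate: seed dispersal kernels and age
structure, snowpack process dynamics, classification error in the cover
maps, spatial autocorrelation of the response beyond what contagion
induces, and real terrain morphology (valleys, ridgelines).  Passing the
recovery tests therefore demonstrates the statistical machinery under a
known logistic driver model, not robustness to every property of real
imagery-derived data.

## Recovery experiments and the exposure response

A spreading front creates a structural confound: over a 19-year window
the raw density-increase response is dominated by *when* the front
reached a cell, and with a band-shaped initial range that arrival time
is essentially elevation.  The recovery experiments therefore use the
per-attempt response: colonization events per exposure-year (a cell-year
in which an absent cell had an occupied neighbour), aggregated over 5×5
blocks and restricted to blocks with ≥ 30 exposure cell-years.  This
ratio estimates the colonization probability itself and isolates the
planted drivers; the observational density response remains the default
for the descriptive pipeline, where the elevation signal is a real
(if mechanistically trivial) part of the pattern.

Experiment 1 plants a dominant single factor — TWI with β = 2, all other
effects zero.  TWI is the natural plant because it is terrain-local and
essentially uncorrelated with the elevation-lapsed climate factors, so
the experiment measures detection power rather than collinear
label-swapping.  Experiment 2 plants only the TWI × Pre_1 interaction
(β = 3).  Both run 20 replicates at 200×200 with consecutive seeds, and
recovery means the planted driver (pair) ranks first — for the
interaction, with the nonlinear-enhancement category.

## Numerical choices and limitations

- Grids are north-up, row-major, cell-centre sampled; points take the
  value of the containing cell; nodata is NaN in memory and an explicit
  sentinel (−9999) in the plain-text ASCII-grid files.
- q values are asserted into [0, 1] (tolerance 1e−9 against rounding)
  on every call; q is undefined (error) when the response is constant.
- Quantile bins with tied values merge (k is reduced with a warning);
  a constant factor collapses to a single stratum.
- The D8 epsilon fill (1e−6 m) makes flow directions deterministic but
  means TWI on perfectly flat synthetic inputs reflects the fill's tie
  ordering rather than physical drainage.
- Real q magnitudes depend on the stratification (breaks and k), so q
  values are comparable only within a configuration; the sensitivity
  sweep quantifies this.
- The pipeline is deterministic given (config, seed): reruns are
  byte-identical.
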