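# Methods

`pleconflict` implements a complete raster pipeline for diagnosing and
forecasting land-space conflict in the "production–living–ecological" (PLE)
framework: reclassification of a six-class land-use map into four PLE
spaces, a grid-based composite conflict index, a coupled Markov +
neural-network + cellular-automata land-use simulation, and a functional
zoning derived from how conflict levels move between two dates.  All stages
run on a synthetic landscape generator, so the full chain is reproducible
and testable without any proprietary land-survey data.

## PLE reclassification

The six primary land-use classes (cultivated, woodland, grassland, water,
construction, unused; codes 1–6, nodata 0) are recoded cell-by-cell into
four functional spaces:

| PLE space | code | land-use classes | vulnerability f |
|---|---|---|---|
| living-production (LP) | 1 | construction | 4 |
| production-ecological (PE) | 2 | cultivated, grassland | 3 |
| ecological-production (EP) | 3 | woodland, water | 2 |
| ecological (ECO) | 4 | unused | 1 |

Grassland's place is genuinely ambiguous at the six-class level: a
barren-grassland reading makes it ecological space, an agro-pastoral
reading production-ecological.  The default mapping uses PE (consistent
with the area bookkeeping of typical PLE studies on plain agricultural
counties); `TABLE1_MAPPING` provides the ECO alternative.  Area accounting
is done in exact cell counts and only converted to km² (and rounded) at
report time; change rates are `100 × (later − earlier) / earlier` and are
reported as undefined when the base area is zero.

## Conflict measurement

The landscape is tiled into square evaluation units (default 1000 m; a
grid of this size balances spatial detail against patch statistics for a
county-scale study area).  Boundary units only partly covered by data are
kept and **all denominators use the full nominal unit area A** — partial
coverage therefore lowers, rather than inflates, their complexity and
vulnerability contributions.

Within each unit, patches are connected components of one PLE class
*clipped at the unit boundary* (8-connectivity by default, 4 available).
Patch area is cell count × cell area; perimeter counts every cell edge
facing a different class, another unit, or nodata.  Three indices follow:

* complexity `SCI = Σ_patches [2 ln(0.25 P) / ln(a)] · (a/A)` — the
  area-weighted mean patch fractal dimension.  A single square patch
  filling the unit gives exactly 1; more convoluted shapes score higher.
  With lengths in metres and cells ≥ 1 m, `ln(a) > 0` always, so the
  expression has no singularity on real inputs.
* vulnerability `SVI = Σ_classes f(class) · a_class / A` with the scores
  in the table above, so `SVI ∈ [0, 4]`.
* stability `SRI = 1 − (PD − PD_min)/(PD_max − PD_min)` where `PD` is
  patch count / A and the extremes are taken over all units of the same
  date; the most fragmented unit scores 0.  A degenerate pool (all PD
  equal) yields SRI = 1 everywhere and is logged.

The composite `SCCI = SCI + SVI − SRI` is min–max normalized to [0, 1]
over a pool of units.  By default the pool spans **all dates jointly**, so
a level-3 unit in one year means the same as in another — the property a
time series of level counts needs; per-date pooling is available.  Levels
cut the normalized index into five equal intervals, half-open with the top
bin closed (`[0, .2), …, [.8, 1]`), labelled weaker/weak/medium/strong/
stronger.

## Land-use simulation

**Demand (quantity) model.**  A first-order Markov chain on class counts:
`P[a,b]` is fitted as the fraction of class-`a` cells at the calibration
start found as `b` at the end; the state vector is advanced by `Pᵀ` once
per calibration interval.  Horizons must be whole multiples of that
interval (the default forward run uses one step, i.e. a horizon equal to
the calibration span).  Totals are conserved exactly; km² demand vectors
are converted to whole cells by largest-remainder rounding.

**Suitability model.**  A single-hidden-layer perceptron (12 logistic
units by default) maps standardized driver values to class membership
probabilities.  Training samples 5 % of cells uniformly (minimum 1000),
topped up with a stratified draw for any class the uniform sample missed.
Predicted probabilities are renormalized so each cell's six probabilities
sum to 1 (classes absent from training have probability 0).

**Allocation (CA) model.**  Each cell's probability of converting to class
`k` is

    TProb[p,k] = sp[p,k] · Ω[p,k] · Inertia[k] · M[c(p),k]

with `Ω` the Moore-window (default 3×3) density of `k` around `p` scaled
by a per-class expansion weight, `Inertia` an adaptive per-class
multiplier, and `M` the scenario's binary allowance matrix used as the
multiplicative complement of a conversion cost.  Each sweep visits
candidate cells in descending best-`TProb` order (ties broken by a seeded
jitter of magnitude 1e-12) and converts a cell to its best under-demand
class while its current class remains over demand; restricted cells never
change and forbidden transitions never occur.  Convergence requires every
class within `max(0.5 % of demand, 10 cells)` of its target; the cap is
300 sweeps, after which the unmet residual per class is reported.

Two numerical choices deserve note:

* *Neighborhood floor.*  `TProb` uses `max(Ω, 0.01)`: the strictly
  multiplicative form deadlocks whenever a class below demand has no
  existing patch adjacent to any donor cell (its Ω is zero everywhere it
  could grow).  The floor lets suitability seed new patches while leaving
  allowance and restriction constraints untouched; `neighborhood_effect`
  itself remains the exact windowed count.
* *Inertia conventions.*  The default (`printed`) update multiplies by
  `D(t−2)/D(t−1)` when `0 > D(t−2) > D(t−1)` and by `D(t−1)/D(t−2)` when
  `D(t−1) > D(t−2) > 0`, where `D` is the signed demand − count gap: a
  class falling further below demand gets boosted, one overshooting
  further gets damped.  An `absolute` variant keys the same multipliers on
  the absolute gap growing.  The two differ only on sign-crossing
  trajectories; both are available because published formulations of the
  adaptive coefficient disagree.

Validation uses Cohen's kappa on the cell-wise confusion matrix between a
simulated and an observed raster.

## Scenarios

Three configurations ship as data: natural development (ND), cultivated-
land protection (CL) and ecological protection (EP).  Each holds a 6×6
allowance matrix (ND freezes construction; EP freezes woodland and
grassland; all diagonals are 1), the neighborhood expansion weights
(0.56, 0.25, 0.36, 0.43, 1, 0.25 — construction expands most readily), a
km² demand vector for a 15-year horizon, and a restriction layer (CL:
basic farmland; EP: ecological reserve).  The shipped restriction layers
are synthetic stand-ins built from the base raster (EP: all woodland and
grassland cells; CL: the spatially coherent half of cultivated cells
selected by a smoothed seeded field).

For synthetic runs, per-scenario demand is derived from the calibrated
Markov matrix masked by the scenario's allowance matrix (probability on
forbidden moves returns to the diagonal).  This makes each scenario's
demand exactly realizable by allowed conversions, so the allocation
problem is feasible by construction.

## Zoning

For each evaluation unit the conflict levels at two dates form a two-digit
code `10·level_t1 + level_t2`.  Fifteen canonical codes map to five zones:

* ecological protection — 11, 21, 41
* ecological conservation — 22, 32, 42
* modern agricultural — 13, 23, 33
* development coordination — 43, 34, 44
* urban optimization — 45, 54, 55

The ten remaining codes (which need not occur in any given run) fall back
on the end-state level (1–2 → conservation, 3 → agricultural, 4 →
coordination, 5 → optimization), preserving the monotone conflict → zone
gradient; a strict mode leaves them unassigned.  Fallback assignments are
flagged in the zone summary.

## Synthetic landscape generator

The generator emulates the input stack of a county-scale study: driver
surfaces, paired categorical rasters, and a known transition structure.

* *Drivers* are Gaussian-smoothed white-noise fields (sigma = the
  autocorrelation range, default 8 cells), every second layer plus a
  linear gradient mimicking broad trends (elevation, distance to city);
  all layers standardized to mean 0, sd 1.
* *Class placement* rank-thresholds per-class affinity scores — a fixed
  seeded linear combination of the drivers plus smoothed noise — so
  realized proportions hit the configured shares exactly up to integer
  rounding, and class membership is a learnable monotone function of the
  drivers.  Default shares (0.770, 0.013, 0.001, 0.095, 0.116, 0.005)
  reproduce the cultivated-dominated structure of a plain agricultural
  county; the default grid is 200×200 cells of 30 m (6 km × 6 km), so the
  1000 m conflict grid tiles it into 36 whole units, and smaller or odd
  extents exercise the partial-unit rule.
* *Evolution* converts, within each source class, the largest-remainder
  quota of cells for each target row entry of the injected transition
  matrix, choosing cells by descending target-class affinity.  Empirical
  transition frequencies therefore match the injected matrix to within one
  cell per entry, and conversions have spatial structure rather than
  salt-and-pepper noise.  The default matrix is mostly diagonal with
  cultivated → construction (0.02) and cultivated → water (0.008) as the
  dominant flows, plus small churn in the trace classes.

What the generator does **not** emulate: real geography (hydrology, road
networks, administrative shapes), anisotropic or long-range spatial
dependence, class-boundary mixing noise, secondary (25-class) legends, and
observation error in the underlying remote-sensing product.  Passing tests
therefore demonstrate that the algorithms are implemented correctly and
that the calibrate → simulate loop recovers known structure — not that the
pipeline's outputs on real data would carry the same accuracy.

## Problem sizes and determinism

Default study sizes: 200×200 cells for the simulation round trip (driver
training on 5 % samples), 500×500 for transition-matrix recovery, 50×50
for brute-force oracle comparisons.  Every stochastic component (field
generation, sampling, network initialization, tie-breaking) is driven by
an explicit seed; identical seeds give bit-identical rasters and byte-
identical artifacts, which the pipeline manifest verifies by content hash.

## Known limitations

* The allocation sweep is deterministic-greedy; a roulette-wheel variant
  common in CA land-use models is not implemented.
* Demand infeasible under a scenario's allowance matrix is reported as a
  residual, not resolved by relaxation.
* `SRI`'s patch-density reading uses patch count per unit; a variant using
  the count of distinct space types is possible but caps the numerator at
  4 and destroys contrast, so it is not the default.
* No cartographic output; rasters are written as plain single-band TIFFs
  with JSON sidecars rather than georeferenced GeoTIFFs.
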