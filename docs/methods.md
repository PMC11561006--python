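# Methods

## Model

The study area is a rectangular lattice Λ of square cells (the case-study
grid is 192 × 202 cells of 5 m). Each cell t carries a year-average
density ω_t ∈ [0, K]: the expected number of individuals seen on the cell
per field trip, averaged over the year's trips. The cap K is the observed
per-cell density on the river transect — total individuals counted on the
river divided by (transect cells × trips) — under the assumption that the
density is maximal on the river. Working with densities instead of
integer counts is what lets the model absorb a whole year of extremely
sparse observations at once: a Poisson point pattern of a handful of
individuals would otherwise seed artificial clusters once neighbor
interactions are introduced.

The energy of a configuration is H = H₀ + V_g:

* H₀(ω) = Σ over unordered 4-neighbor pairs (ω_{t₁} − ω_{t₂})². Each pair
  contributes once. A cell adjacent to the river contributes one term
  (ω_t − K)² per river neighbor, so a cell flanked by the river on two
  sides contributes two boundary terms (the boundary sums iterate over
  incidences, not cells).
* V_g(ω) = g Σ_t d_t² ω_t, with d_t the distance of cell t to the river
  and g ≥ 0 the attraction strength. The quadratic shape is a modeling
  hypothesis (leading term of an expansion around the minimum); with data
  this sparse only one free parameter is identifiable.

The probability law is the Gibbs measure π(ω) ∝ exp(−H(ω)/T).
Conditioning on the river values (fixed at K) factorizes π over the
4-connected off-river regions, because cells of different regions are
never neighbors; the package exploits this by sampling each region
independently (verified as an exact energy identity in the tests). The
normalization Z is never computed — everything works through energy
differences.

### Distance to the river

d_t = M_t + A_t, where M_t is the minimal absolute column offset from t
to any river cell and A_t the absolute row offset to a river cell
achieving that column minimum (ties broken by the smallest row offset;
d does not depend on further tie-breaking). Distances are in cell units
(center-to-center offsets), not meters: the coupling g absorbs the
spatial scale, and it is calibrated empirically anyway. d = 0 exactly on
the river, and d ≥ 1 on every off-river cell.

### Coordinates

Rows count from the north edge, columns from the west edge, 0-based.
When a grid is UTM-anchored, a point maps to the cell
(round((northing_max − northing)/cell), round((easting − easting_min)/cell));
nearest-integer rounding is the convention that reproduces all five
published parcel coordinates of the case study.

## Sampling

Single-site Metropolis ("Gibbs sampling" in the annealing literature):
one *sweep* visits every cell of a region once in a fixed periodic order;
at each cell a proposal x is drawn uniformly on [0, K], accepted outright
if it lowers H and with probability exp(−ΔH/T) otherwise (the acceptance
uniform is drawn only in that second case, so the stream order is
proposal-first and runs are bit-reproducible from the seed). ΔH is
computed from the cell's ≤ 4 neighbor terms, its river-boundary moments
and its potential term — O(1) per proposal. Proposals live in [0, K], so
the chain can never leave the box. The energy recorded per sweep is
recomputed exactly at the end of the sweep rather than accumulated from
deltas, so the trace carries no drift; full-grid energies elsewhere use
numpy's pairwise summation.

The visit order is a breadth-first layering from the river: layer 0 is
every region cell adjacent to the river, layer ℓ+1 the unvisited
neighbors of earlier layers; within a layer, row-major order. Sweeping
river-outward propagates the boundary information into the region within
a single sweep, which is what makes the energy descend fast. Any ordering
with these layering properties is admissible; the row-major tie-break
just makes it deterministic. A region that never touches the river has no
boundary to condition on and is rejected as a configuration error.

The year-average density estimate ω̂ is the arithmetic mean of the
end-of-sweep states over the last `tail_sweeps` sweeps, accumulated as a
running mean (the state history is never stored; a bounded tail window
can optionally be retained for diagnostics). Averaging end-of-sweep
states rather than every single-site state is statistically equivalent at
stationarity and m-times cheaper.

### Temperatures and relaxation

T controls how concentrated π is on low-energy states. The package's
annealing is deliberately minimal, a single temperature drop: a warmer
chain (T₁) from the zero state approaches the minimizer quickly, then a
colder chain (T₂), warm-started from the first chain's tail average,
freezes the remaining thermal fluctuations. Both temperatures matter:

* too warm, and the tail average carries thermal noise of scale
  ~√(T/8) per cell plus slowly-mixing smooth fluctuations;
* too cold, and the uniform-proposal kernel is acceptance-starved — the
  acceptance probability of an improving proposal shrinks with the
  distance to the local optimum, and the smooth, low-energy deformations
  of the field (which cost ~δ²/W² per cell over a region of width W)
  relax extremely slowly. In practice a chain started from zero at
  T = 1e-7 on a 400-cell region barely moves its far side in thousands
  of sweeps.

Measured on a 20 × 20-cell region with K = 0.113: T₁ = 1e-4 and
T₂ = 1e-6 with 200 000 sweeps per stage bring the free-case tail average
within ~2% of the exact constant-K minimizer (seeds 0–9), in ~10 s.
These are the package's desk-scale defaults for that geometry size; the
case-study preset records the reference temperatures calibrated on the
full-scale geometry (T₁ = 4.75e-6, T₂ = 2e-8), which are tied to that
unpublished raster and its ~13 700-cell regions and are shipped as data,
not as targets.

T₁ is selected exactly as the free case prescribes: run the g = 0 chain
from zero at each candidate temperature (default grid: log-spaced
1e-3 … 1e-9) and keep the candidate with the lowest tail-average energy —
usable because the free-case minimizer is known in closed form (constant
K, H = 0). T₂ is user-supplied or defaults to T₁/100; the reference
preset's ratio (~237) is of the same order.

## Calibrating the coupling

The target is the year-average expected count over the surveyed parcels:
parcel individuals / trips (0.3 in the case study). The parcel
expectation of a density field is simply its sum over the parcel cells.
Attraction can only pull density off the parcels, so the expectation is
non-increasing in g (checked at run time, not proved); a target above the
free-case expectation is reported as infeasible. The estimator:

1. evaluates g = 0; accepts 0 if already within tolerance;
2. doubles g from 1e-10 until the expectation first drops below the
   target (a scale-free bracket);
3. bisects the bracket until |achieved − target| ≤ tol (default 0.01
   expected individuals, absolute) or the bracket is relatively tiny.

Every evaluation runs the same seeded two-stage chain (T₁ from zero, T₂
warm-started), so the whole procedure is deterministic given (seed,
config). The published workflow tuned g by manual scanning; the bracket +
bisection automation is this package's choice, made for reproducibility.
When producing a full map, the coupling calibrated on the parcel-bearing
region is applied to all regions (only one region has field data).

## Realizations and rendering

From ω̂ (densities per off-river cell):

* **whole-year counts**: each cell independently draws
  Poisson(trips · ω̂_t) — the year-intensity field is trips times the
  per-trip density;
* **single-trip presences**: each cell is occupied iff an independent
  uniform draw is ≤ ω̂_t, i.e. Bernoulli(ω̂_t), valid because K < 1;
* **heat map**: 7 rainbow bins (red → violet) on the half-open intervals
  ((s/7)K, ((s+1)/7)K], s = 0…6; an exact zero falls outside every
  interval and is assigned to bin 0 so empty cells render at the lowest
  intensity. River cells are excluded from draws (their density is the
  boundary constant, already summarized by K) and rendered black. Dots
  are jittered uniformly inside their cell square — within-cell placement
  carries no information.

## Synthetic geometries

The real river raster of the case study is not published, so the
generator emulates its qualitative structure: a 4-connected band of
configurable width crossing the grid top to bottom along a random
row-monotone lattice path (elbow cells keep connectivity across column
shifts), optionally forking once so the two diverging branches enclose a
wedge — two regions without the fork, three or four with it, mirroring
the real geometry's four river-separated regions. Planted-truth scenarios
add parcels spread over distinct river distances in the largest region
and a reference density field generated by the same two-stage recipe the
calibration uses, so recovery experiments compare like with like.

What the generator does *not* emulate: real channel curvature and width
variation, orography (the real study area is a canyon whose terrain
visibly modulates density), and any observation error. Passing tests
therefore demonstrate that the machinery is correct — energies exact,
sampler stationary, calibration able to recover a known coupling under
the model's own assumptions — not that the model is adequate for any
particular real landscape.

## Numerical choices and degenerate inputs

* Region numbering is deterministic (descending size, ties by first
  row-major cell) so "region 1" is stable across runs.
* Distance ties: among river cells at the minimal column offset, the
  smallest row offset wins.
* ΔH = 0 proposals are accepted (exp(0) = 1), consistent with the
  acceptance rule's ≤.
* Single-cell regions are legal; their chain is a sequence of
  Metropolis-filtered independent draws.
* An all-river mask yields zero regions; an all-land mask yields one
  region covering the grid (with no river it cannot be sampled — the
  distance field and ordering both require a river).
* Desk-scale problem sizes used throughout the tests: regions of ~200–400
  cells, 2e4–2e5 sweeps per stage, chosen as the smallest sizes at which
  the convergence and recovery properties hold with comfortable margins.
* Seeds: a single seeded generator per chain; multi-chain procedures
  derive per-stage/per-region streams with a splitting sequence.

## Limitations

* The quadratic well with one coupling is the entire covariate model; no
  terrain, vegetation or detection-probability effects.
* No uncertainty quantification for the estimated coupling — the
  calibration matches a point target, as the original workflow did.
* The ergodic/annealing theory motivates but does not guarantee the
  single-drop temperature scheme; correctness at desk scale is
  established empirically by the test suite (quadrature comparison,
  free-case minimizer, monotone coupling response).
* Heat-map rendering is a plain raster image; no GIS export.
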