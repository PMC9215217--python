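# Methods

This note records the model, the numerical choices, and the design
decisions behind `oceanot`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Distributions on grids and depth axes

A surface field lives on a rectilinear longitude–latitude grid with a
boolean validity mask; a depth profile lives on a strictly increasing
depth axis. Cells are enumerated row-major with latitude descending and
longitude ascending, a fixed convention that makes transport plans and
distance matrices byte-reproducible across runs.

Normalization divides each valid cell value by the total over valid cells.
Masked cells (land, coastline buffers) and missing values (clouds) are
treated identically — both are removed from the support before
normalization — because upstream the two are rarely distinguishable and a
single unified mask keeps the support definition simple. Zero-valued valid
cells stay in the support with probability zero; the solver drops them
before building the LP, which cannot change the optimum.

Values are normalized on their native concentration scale (no log
transform): the distribution being transported is "share of total
chlorophyll per cell", which is the physically meaningful quantity for a
mass-movement interpretation.

Colocalization of model output to irregular in-situ casts averages all
model records within ±2 days and ±5 m of each observation (closed
intervals, unweighted arithmetic mean); observations with an empty window
are dropped and reported rather than imputed.

## Base distances

Map base distances are great-circle kilometres from the haversine formula
on a sphere of radius 6371.0088 km (the IUGG mean radius). A sphere rather
than an ellipsoid keeps the metric exactly symmetric and the discrepancy
(< 0.6%) is far below the grid resolutions this package targets. The
haversine form is numerically stable near zero separation, which matters
because most mass in a typical plan moves between nearby cells. Depth base
distances are |Δz| in metres. Transport costs are squared base distances,
making the resulting distance the 2-Wasserstein metric with the units of
the base distance itself.

Arcs longer than a threshold can be forbidden (set to +∞) to restrict
transport to local moves.

## The exact solver

The transportation LP is solved by a transportation simplex — the network
simplex specialized to the dense bipartite transportation polytope:

- **Initial solution**: Vogel's approximation (allocate where the regret of
  not using the cheapest remaining cell is largest). On exhausted-row/column
  ties only the row is removed, so the basis remains a spanning tree of
  m + n − 1 arcs through degenerate allocations.
- **Pivoting**: dual potentials are propagated through the basis tree, the
  most negative reduced cost enters, and the leaving arc is the minimum-flow
  arc on the alternating cycle (ties broken by lowest arc index).
- **Anti-cycling**: supplies are perturbed by ε = 1e−7 × (minimum positive
  mass), with the balancing amount added to the last demand. After
  optimality, flows are recomputed *exactly* for the unperturbed marginals
  by leaf elimination on the final basis tree, so plan marginals match P and
  Q to ~1e−15 regardless of ε.
- **Optimality tolerance**: pivoting stops when the most negative reduced
  cost exceeds −1e−11·(1 + max cost); since every pivot moves at most unit
  mass, the objective is then within ~1e−11·(cost scale) of the optimum.
  The acceptance battery measures the realized gap against an independent
  dense-LP solve (scipy/HiGHS): it is at machine precision.
- **Forbidden arcs**: feasibility is decided before solving by an integer
  max-flow on the allowed-arc graph (masses scaled by 1e9, scipy's
  csgraph); inside the simplex forbidden arcs carry a large finite
  surrogate cost, and the solve asserts afterwards that none carries mass.
  This keeps the pricing dense and simple while preserving the exclusion
  semantics; a genuinely infeasible instance raises before the simplex
  runs.

Zero-probability cells are dropped from the LP support. When several
optimal plans exist (cost ties), the returned plan is the basic solution
the simplex terminates with — deterministic for fixed inputs, but only the
objective (and hence W2) is unique; visualization consumers should treat
the arrows as *one* optimal scenario.

Two independent oracles verify the solver in tests and in the acceptance
script and are never used as the production path: a generic dense LP solve
(HiGHS via scipy) and, for one-dimensional supports, the closed-form
quantile representation W2² = ∫₀¹ (F_P⁻¹ − F_Q⁻¹)² dt evaluated exactly
over the merged CDF breakpoints.

## Plan summaries

A plan's *moving* arcs are those with positive base distance; a zero-cost
plan therefore has an empty summary. The "top fraction" split sorts moving
arcs by mass (descending, ties by source/target index) and takes the
smallest prefix whose cumulative mass reaches the requested fraction of
total moved mass — the bold arrows of a transport map. Pooling sums arc
masses by (source, target) endpoint across many plans, which exposes
systematic displacement (e.g. one data source's chlorophyll maximum
consistently sitting deeper than the other's).

## RMSE and classical MDS

RMSE is ((1/n) Σ (P_i − Q_i)²)^(1/2) over the n shared valid cells and
requires identical supports; mismatched supports raise with an instruction
to reconcile rather than silently intersecting. Classical MDS
eigendecomposes B = −½ J D² J. Negative eigenvalues — expected, since
Wasserstein distance matrices need not be Euclidean-embeddable — are
clamped to zero, the standard Torgerson convention. Axis signs are fixed
deterministically (largest-magnitude coordinate positive); tests compare
embedded *distances*, never raw coordinates, because the embedding is only
defined up to rigid motion. MDS consumes the distances D themselves, not
D²; squared input is a caller choice.

## Seasonal-trend regression

All N(N−1)/2 upper-triangle pairs enter one OLS fit of

D_ab ~ β0 + β1·total_lag + Σ_{k=0}^{6} β2_k·1(calendar_lag = k),  Σ β2_k = 0.

The sum-to-zero constraint is imposed by reparameterization (indicator
minus last-level indicator), so the fit is ordinary least squares on a
full-rank design and the last coefficient and its standard error are
recovered from the coefficient covariance. Calendar lags 0 and 6 occur
half as often as 1–5 on the 12-month circle; no reweighting is applied
(plain OLS, as is conventional). Pairs sharing a map are statistically
dependent, and ordering duplication would not change point estimates —
upper-triangle pairs only are used. Standard errors are the usual OLS ones
and should be read accordingly (no dependence correction); the simulation
in the acceptance battery shows the ±3 SE interval covers the true slope
comfortably under independent noise. If some calendar-lag levels are
absent from the data, the constraint is applied over the observed levels
and unobserved coefficients are reported as zero; the usual ≥13
consecutive-month designs observe all seven levels.

## Provinces and boundaries

K-means clusters the raw per-cell values (a 1-D feature — the front being
detected is a *value* front, so coordinates are deliberately not
features), 10 restarts, fixed seed, labels renumbered so cluster 1 has the
lowest mean. A log10 option exists for strongly skewed fields. Boundary
cells are valid cells with at least one valid 4-neighbor of a different
label: a two-sided, label-symmetric definition with the simplest
connectivity; the boundary field puts uniform mass on these cells.
Comparing two maps' boundary fields with W2 measures front displacement in
kilometres while ignoring within-province magnitude differences entirely.

## Depth profiles and the DCM

The deep chlorophyll maximum is the depth of the profile's maximum value
(argmax is invariant to normalization), ties resolved to the shallowest
depth. Profile W2 uses exact transport over |Δz| and is verified against
the quantile closed form; RMSE needs a shared (colocalized) depth grid.
The DCM regressions are simple least squares of each distance measure on
the absolute DCM difference (signed available as a flag); R² is the
squared Pearson correlation.

## Synthetic data: what it emulates, and what it does not

The generators are deterministic given their spec and seed, produce
strictly positive fields, and emulate the *structure* the analyses rely
on, not the statistics of real ocean colour:

- **Background**: a logistic north-high latitudinal front (low plateau
  0.05, high 1.0, front at 25° N, width 8°) standing in for a
  transition-zone chlorophyll gradient.
- **Patch toy**: a circular Gaussian patch (amplitude 2, σ = 350 km,
  truncated at 3σ, centred at 150° W, 10° S) added to the background and
  displaced east by up to 40° of longitude. The truncation makes patch
  supports exactly disjoint beyond ~19.3° of shift, which is what produces
  the RMSE plateau; σ was chosen so that plateau onset falls near a 20°
  shift. The toy grid is a 76° × 68° central-Pacific box at 4° spacing
  (360 cells) — small enough that the full displacement series solves in
  well under a minute, large enough that a 40° displacement spans many
  cells. W2 growth is mildly sublinear at the longest shifts (squared-cost
  transport can relay patch mass through background mass), which is why
  linearity is asserted as R² of a linear fit rather than as exact
  proportionality.
- **Seasonal series**: the patch's longitude follows A·sin(2π·month/12)
  plus a linear drift per month plus seeded Gaussian jitter, amplitudes in
  km at the patch latitude (defaults: A = 600 km, no drift, no noise) — a
  minimal test bed for the seasonal-trend regression.
- **Profiles**: a unit-height Gaussian bump at the requested DCM depth
  (σ = 30 m) over a small exponentially decaying surface baseline, with
  optional multiplicative lognormal noise (keeps values positive),
  normalized to sum to one.

Passing tests on these generators demonstrates the *mathematical*
behaviour of the methods (exactness, metric structure, saturation
contrast, coefficient recovery); it does not validate conclusions about
any real satellite product, model run or mooring record, whose spatial
spectra, missingness and error structure the generators make no attempt to
match.

## Numerical conventions and degenerate inputs

- Probabilities must sum to 1 within 1e−12 at construction; the solver
  renormalizes once (logged) and rejects mass imbalances beyond 1e−6.
- Plan marginals are checked to 1e−10 inside `solve_transport`; a
  violation is an internal error, not a warning.
- All-zero fields, constant fields passed to clustering, single-cluster
  boundary extraction, constant DCM predictors and zero denominator slopes
  raise informative errors rather than returning NaN.
- CSV output uses 17 significant digits and CSV input uses round-trip
  float parsing, so file round-trips are bit-exact.
- NetCDF I/O uses xarray's `scipy` engine (NetCDF3): portable and free of
  binary dependencies; fields with CF-style `lat`/`lon` coordinates from
  other producers are read, with latitude re-sorted to the package's
  descending convention.

## Known limitations

- The dense transportation simplex is exact but O(m·n) *per pivot* in
  pricing; it is comfortable to ~1000 support cells per side and not
  intended for 10⁴-cell maps. The masked-arc mechanism reduces cost but
  not pricing density.
- Multiple optimal plans are not canonicalized.
- Regression standard errors ignore the dependence between pairs sharing a
  map.
- Regridding between unequal-resolution products is out of scope; fields
  compared by RMSE must already share a grid.
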