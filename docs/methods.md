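# Methods

## The model

Sightings are modelled as a spatio-temporal point process whose
conditional intensity factorizes into an intercept, a log-linear habitat
term, a self-excitation term, and a log-linear detection-bias term:

λ(x,t | H_t) = λ0 · q(x,t) · r(x,t | H_t) · b(x,t),
log q = γᵀe(x), log b = βᵀd(x),
r(x,t|H_t) = ∏_{j: t_j = t−1} {1 + [θ(t) − 1]·f(‖x − x_j‖)},
f(s) = exp(−s/φ) for s < u, 0 otherwise.

Assumptions worth making explicit:

- **Covariates are static.** e(x) and d(x) do not change over the study
  period; all temporal variation in the intensity comes from the
  interaction term and the seasonal switch in θ(t).
- **One-period memory.** Only the immediately preceding month's pattern
  enters r. The period is one calendar month (the seasonal θ switch is
  sub-annual, so a yearly period would be incoherent; a `period` option
  retains the yearly reading). The first period has no history, so r ≡ 1
  there.
- **Hard interaction range.** f is truncated exactly at u = √A
  (≈ 0.5916 km for A = 0.35 km²), with the boundary point in the zero
  branch. θ(t) > 0 is the only constraint; 0 < θ < 1 gives inhibition.
- **Detection bias is separable and static**: b = exp(βᵀd) with d the
  standardized distance to primary roads. Predictions of true density
  use λ0·q·r with b removed.

## Thinning

Within each calendar month, records closer than the home-range diameter
2·√(A/π) are collapsed by a greedy sequential scan in ascending
report-date order (ties by record id): a record is kept iff it is at
least that distance from every record already kept that month. The rule
is deliberately not applied across months (home ranges overlap over
time), so one animal can contribute up to 12 records per year. Greedy
scanning is deterministic and O(n²) per month; it keeps the earliest
record of each within-month cluster, which matches the "repeat sightings
of one animal" reading of the rule.

## Discretization and fitting

The observation window is the convex hull of the sightings dilated by a
buffer (default 3 km), discretized into a square grid (default 1 km) with
cell-centre membership. The integral in the partial likelihood is
evaluated per event period by midpoint quadrature (cell-centre value ×
cell area), and events are attributed the values of their containing
cell's centre. Using the same discretization in numerator and denominator
makes the uniform-model identity Lp = −N·log|A| exact and keeps the
estimator internally consistent with the cell-wise simulator.

Maximization is quasi-Newton (L-BFGS) over ψ = (γ, β, log θ1, log θ2,
log φ) — the log transforms enforce positivity without bounds — from a
null start (zeros; log φ starts at log u), gradient tolerance 1e-6,
iteration cap 500. All interaction products are accumulated in log space
(`log1p`) so large histories cannot overflow. λ0 is the moment estimator
N / Σ_t ∫ q·b·r dx, computed on the same quadrature; by construction the
expected bias-included total then equals N exactly.

Standard errors are Wald-type from a central-difference Hessian of Lp at
the optimum. The Hessian is eigendecomposed and directions of
numerically non-positive curvature — flat ridges, e.g. φ when θ̂ ≈ 1 —
are assigned infinite variance instead of contaminating the inverse; the
affected parameters report infinite standard errors, which is the honest
statement of what the data determine. θ and φ intervals are mapped to the
natural scale through exp, so they are positive and asymmetric. λ0 is a
plug-in and gets no interval.

Covariate standardization uses the mean and the n−1 standard deviation
over masked-in grid cells; masked-out cells carry NaN.

## The synthetic-data generator

The generator emulates the three inputs the pipeline consumes:

- **Covariate fields**: seeded mixtures of low-frequency cosine waves and
  Gaussian bumps, smoothly saturated (tanh) at ±1.2 internal standard
  deviations. The saturation reflects that real habitat covariates
  (temperature, elevation, canopy cover) are bounded; under a log-linear
  intensity, Gaussian-tailed fields produce hotspot cells in which the
  multiplicative self-excitation is locally supercritical and most
  realizations diverge.
- **Roads**: random chords across the study region's bounding box, from
  which the distance-to-roads bias covariate is computed exactly.
- **Sightings**: per period, a Poisson count per cell with mean
  λ(cell)·cell area (bias included if the observations are meant to be
  biased), events placed uniformly within their cell, and the realized
  pattern fed forward as the next period's history. Cell-wise Poisson
  sampling matches the piecewise-constant discretization used in fitting,
  so parameter recovery tests the estimator, not the quadrature.

A self-exciting process with per-neighbour factor up to θ is only
conditionally stable: a realization can ignite a chain reaction in a
high-intensity cell. The simulator guards this with a cap on the expected
count per period, and `simulate_stable` redraws the event substream
(deterministically, seed + 7919·attempt) until a realization survives —
i.e., it samples the process conditioned on non-explosion, the standard
device for near-critical Hawkes-type simulation. One global seed drives
named substreams for covariates, roads and events, so components can be
regenerated independently.

What the generator does **not** emulate: animal demography and dispersal,
reporting-rate drift over years, duplicate records beyond the
road-distance bias, irregular (non-square) study regions, and
measurement error in coordinates or dates. Passing recovery tests
therefore show that the estimator inverts its own generative model at
realistic sample sizes — not that the model is correct for any particular
real dataset.

## Study conditions used by the tests

- **Fixed-seed recovery**: 30×30 km grid at 1 km resolution, 36 monthly
  periods, two density covariates, one bias covariate, truth
  (γ1, γ2, β, θ1, θ2, φ) = (0.6, −0.4, −0.7, 2.0, 2.5, 0.4), λ0
  calibrated analytically (before any fitting) as
  target / (T · Σ q·b·Δx) with a target of 3,000 expected events. The
  target sits at the upper end of the realistic range for this window
  because the interaction parameters are informed only by event pairs in
  consecutive months within u ≈ 0.6 km: at ~2,000 events (θ, φ) sit on a
  weak-identifiability ridge (θ̂ low, φ̂ → ∞ can fit individual
  realizations better than the truth), while at ~3,000 events recovery is
  stable.
- **Coverage study**: 20 replicates at 20×20 km, 24 periods, ≈670 events
  each — coverage of the Wald intervals is a property of the interval
  construction, not of the problem size, and the reduced size keeps the
  replicate study inexpensive (~90 s).
- Oracle-equivalence checks use ≤5×5 grids with ≤6 events against a
  literal double-loop implementation of the likelihood.

## Numerical choices and degenerate inputs

- Quadrature: midpoint rule at covariate resolution; finer quadrature is
  a refinement of the grid, not a separate option.
- Tie-breaks: thinning order is (date, record id); the kernel boundary
  s = u maps to 0; category bins are left-closed right-open with an
  open-ended last bin, so every cell falls in exactly one class and rows
  sum to 100%.
- Degenerate inputs raise early: constant covariate layers (zero
  variance), fewer than 3 non-collinear points for the hull, grids with
  no interior cell, events outside the masked region, empty sighting
  files, inverted year ranges.
- Determinism: given the data and start, fitting is deterministic;
  given a seed, simulation is bit-reproducible.

## Known limitations

- Thinning is greedy, not a maximum independent set; it can retain
  slightly fewer points than the optimum, but is deterministic and
  order-faithful to the reporting dates.
- Cell-centre attribution limits how much of the kernel shape (φ) is
  observable on a grid comparable to the interaction range; φ is the
  least well determined parameter and its intervals are wide.
- The partial likelihood conditions on per-period totals, so λ0 carries
  no likelihood-based uncertainty; its plug-in estimate inherits (and
  understates) the uncertainty of the shape parameters.
- Wald intervals rely on local curvature; in flat directions they are
  reported as infinite rather than approximated.
- The local equirectangular lon/lat projection is adequate for regions a
  few hundred km across; continental-scale inputs should be projected
  upstream.
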