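# Methods

## Climate decomposition

The decomposition treats a gridded seasonal climate variable as global mean
plus three additive parts: a time-invariant spatial surface (each cell's
long-term anomaly), a space-invariant annual anomaly (each year's
all-cell mean), and a cell-by-year residual.  Two year ranges are involved
and are deliberately independent configuration: the *centering* window over
which the global mean and per-cell means are taken (long, e.g. 48 years)
and the *study* window over which temporal/residual components are exposed
(the years with survey data, e.g. 23 years).  The temporal component is
computed for all centering years internally but only study years are
exposed.  The algebra gives three identities used throughout the tests:
the spatial component sums to zero over cells, the residual averages to
zero over cells within each year, and global mean + spatial + temporal +
residual reconstructs the raw values exactly.  Missing cells inside the
centering window are a hard error — the identities assume a complete grid
and no imputation rule is defensible without knowing the gap structure.
Aggregation from daily series uses the seasonal mean for temperature and
the seasonal sum for precipitation over May–July or May–June (inclusive,
leap-aware), and a previous-year variant reads the temporal and residual
components of year t−1 while leaving the spatial surface unchanged;
route-years whose lagged source year is unavailable are dropped and
counted.

Numerics: double precision throughout; the identities are asserted at
1e−10 and oracle agreement at 1e−12.  numpy's pairwise summation in `mean`
keeps accumulation error far below these tolerances at the grid sizes
involved (≤ a few thousand cells here; the method itself is O(NT) and
would scale to ~10⁶ cells).

## Design assembly

The count-part design is: intercept; six climate mains (spatial, temporal,
residual × temperature, precipitation); one temperature×precipitation
interaction per component; a second-order polynomial in (standardized)
year; Survey (Point vs Line) and Unit (Individual vs Pair) protocol
dummies with Line/Pair as reference; habitat covariates; and log survey
effort as offset.  The zero-inflation design drops only the protocol
dummies (protocol should not affect whether zeros are recorded).
Continuous covariates are z-standardized after assembly over all retained
route-years, and the constants are stored on the fitted model so
prediction grids can standardize raw component values consistently.
Interactions are products of the standardized mains; year² is the square
of standardized year, itself re-standardized — a cheap orthogonalization
that keeps the design's VIFs moderate.  Elevation is excluded by default
(it is collinear with spatial temperature); habitat subsets are
configuration, not code, since real analyses pick them per species.

Land-cover handling: the 44 CORINE classes map via a shipped, editable
CSV to seven pooled categories (sparsely vegetated mountain, mountain
vegetation, deciduous forest, other forest, wetlands, inland waters,
agriculture) plus "other/sea"; survey years match land-cover epochs as
1996–2003→2000, 2004–2009→2006, 2010–2015→2012, 2016–2018→2018.  Buffer
summaries use cell-center-in-circle membership with no partial-cell
weighting: the rule is exactly enumerable, which keeps the test oracle
trivial, and at 300 m radius on a 100 m raster the discretization error
is small relative to land-cover classification error.  VIFs are computed
as 1/(1−R²) from leave-one-out regressions on centered columns; exact
collinearity reports ∞ and a flag rather than crashing.

## Count mixed models

Four error structures share one linear predictor: Poisson, NB2
(Var = μ + μ²/θ), and their zero-inflated mixtures with
π = logistic(x_zi'γ).  NB2 was chosen as the negative-binomial
parameterization because it is the convention of the mixed-model software
this class of analysis is normally fitted with.  The route random
intercept makes the likelihood a product over routes of one-dimensional
integrals; each is computed by adaptive Gauss–Hermite quadrature centered
at the route's conditional mode with scale from the curvature there
(order 1 = Laplace; default order 7, which agrees with order 25 to ~1e−9
on the test problems).  Modes are found by a vectorized damped Newton
iteration across all routes simultaneously; the conditional log-density
is concave in u for the base families, and the zero-inflated zero-count
rows (whose curvature can locally change sign) are handled by step
halving against the objective.

Optimization is L-BFGS-B over (β, γ, log θ, log σ_u) with finite-difference
gradients, warm-started conditional modes, bounds log θ ∈ [−8, 15] and
log σ_u ∈ [−8, 3], ftol 1e−11, and up to 5 jittered restarts; starting
values come from an internal Poisson IRLS (β), a moment estimate (θ), the
zero fraction (γ intercept), and σ_u = 0.3.  σ_u = 0 degenerates exactly
to the fixed-effect likelihood.  Wald covariance comes from a
central finite-difference Hessian of the negative log-likelihood at the
optimum; in the recovery study the resulting 95% intervals cover at
~95%.

AIC selection: the four families are fitted with identical covariates and
ranked; ties under 1e−6 break toward fewer parameters; non-convergent
families are excluded with a warning.  Covariate selection is backward
elimination over whole component×variable blocks (a block drop removes the
main effect and any interaction involving it, so an interaction is never
retained without both mains), stopping when no single drop lowers AIC.
Block-backward was chosen because the retention of whole components per
variable is the scientific reporting unit; note that AIC retains a
true-null single-parameter block with probability ≈ exp(−1) ≈ 0.16, which
bounds how often a null component can be reported absent.

Paired Point/Line rows from the same route share one random intercept
(they are spatially dependent surveys of the same place); a configuration
flag can force the Poisson family for species whose zero-inflated fits
fail.

## Effect grids, classification, and diagnostics

For each component, abundance is predicted on a 10×10 grid of evenly
spaced temperature×precipitation values between the component's observed
minimum and maximum: for the spatial sweep the anomaly components are set
to (raw) zero; for the temporal/residual sweeps the spatial component
keeps each route's observed value.  All other covariates sit at typical
values — medians of the standardized continuous columns, reference levels
for factors, mean log-effort — and random effects are excluded
(population-level effects are the target); predictions are summed over
routes at common effort.  Single-variable profiles fix the non-varied
variable at the grid level nearest raw zero (anomaly components) or
nearest the mean level (spatial component); averaging over the other
variable's levels is the documented alternative.

Spearman correlations compare grids pairwise over three gradient sets
(joint surface, temperature profile, precipitation profile).  Components
dropped in selection follow the reporting convention: one absent → r_s = 0
with a flag, both absent → r_s = 1 with a flag.  Classification uses the
spatial-vs-temporal correlation along the temperature gradient:
consistent above 0.5, opposite below −0.5, otherwise complex/none, plus a
cold/warm label from the temperature half of the spatial grid's abundance
maximum.  One exactness caveat: with both variables varying, the joint
100-cell rank order of a·i+b·j depends on the ratio of level spacings, so
two grids with equal coefficients but different observed ranges can differ
by adjacent rank swaps (r_s ≈ 0.9998, not exactly 1); the single-variable
profiles are exactly rank-identical and are what classification uses.

Performance screening follows the fixed thresholds: within-sample Pearson
r ≥ 0.4 per country and ≥ 0.5 pooled (random effects at conditional
modes).  Leave-one-year-out CV refits without each year and predicts it
with training-mode random effects for known routes and u = 0 for unseen
ones (the unbiased population-level choice).  Moran's I uses
inverse-distance weights by default (k-nearest optional), E[I] = −1/(n−1),
and a two-sided permutation p-value with 999 permutations.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
a climate cube that is exactly spatial surface + shared annual anomaly +
residual noise (so decomposition recovers the pieces by construction);
temperature and precipitation anomalies drawn jointly with correlation
−0.3 (warm breeding seasons tend drier); a 48-year centering window
containing a 23-year study window; three countries with shares
0.27/0.41/0.32 of routes and scheme start years 1996 (SE) vs 2006 (NO,
FI); paired Point/Line rows for NO sharing a route id and cell; counts as
individuals in SE and pairs elsewhere; ~85% route-year coverage; integer
effort 4–12 per route-year; and counts drawn from the fitted model class
itself with a route random intercept (σ_u = 0.5), NB dispersion θ = 1.5,
and a logit-linear structural-zero process when requested.  The default
spatial surface is a linear north–south gradient (−6 °C, +120 mm across
the grid) plus smooth low-frequency cosine structure, emulating the
dominant latitudinal pattern of a Fennoscandian-type region without
geodesy; residual noise is iid by default with an optional Gaussian
smoothing length (a free knob — the real residual correlation range is
unknown).

Deliberately not emulated: observer detectability and its phenology
dependence (treated as constant, as in the underlying analysis), route
geometry (one cell per route; buffering is exercised separately on toy
rasters), migration, density dependence, and spatially correlated random
effects.  Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated assumptions — not
robustness to detection artefacts or spatial confounding in real surveys.

Seeding: one master seed; per-stage streams derived via
`SeedSequence(entropy=seed, spawn_key=(stage,))` so each stage is
independently reproducible.

## Scenario simulator

Abundance responds through two linear channels,
A(t) = a0 + b_slow·L(t−delay) + b_fast·T(t), floored at zero, where L is
the long-term average temperature series: on the period timescale the
input series is already the long-term average (L = T), on the annual
timescale L is a trailing mean (default: all years up to the current).
The four response types set (b_slow, b_fast, delay) accordingly; "mixed"
uses opposite signs.  The space-for-time forecast is an ordinary
least-squares fit of baseline abundance on baseline temperature across
sites, applied to period averages (static) or annual values (dynamic);
it is identical across response types by construction.  A period is valid
when the maximum relative error across sites is within tolerance (exact,
1e−8, by default; 5% is the suggested noisy setting).  In the noiseless
limit this reproduces the expected truth table: static forecasts are
valid throughout for responses without a delay and left-truncated for
delayed/mixed responses; dynamic forecasts are valid only for fast
responses.  Right truncation (a changing species–climate relationship) is
representable by a slope-change option but off by default.

## Study sizes

The simulation studies use: parameter recovery at 300 routes × 15 years
(≈4,800 route-years), 20 replicates; family selection at 40 routes × 6
years, 50 replicates per generating family; classification recovery at 70
routes × 8 years, 20 replicates × 3 archetypes (block selection run for
the null archetype); leave-one-year-out CV at 60 routes × 8 years with
constant effort.  These sizes keep Monte-Carlo error well below the
effects being checked while a full study completes in minutes on one
core.

## Known limitations

- The AGH integral is one-dimensional by design; crossed or spatially
  correlated random effects are out of scope.
- Finite-difference gradients make each fit O(p) likelihood evaluations
  per iteration; fine at p ≲ 25, not intended for hundreds of covariates.
- Backward block elimination explores a single path; with strongly
  collinear blocks the retained set can depend on drop order.
- The zero-inflation part shares the count part's covariates; separate
  zi-part selection is not implemented.
- Buffer summaries assume planar coordinates; no geodesic corrections.
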