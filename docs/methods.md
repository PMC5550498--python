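# Methods

`steppm` fits hierarchical Bayesian Poisson space–time models to areal
count panels and provides the exploratory spatial statistics and the
synthetic-data machinery needed to exercise them end to end. This note
records the model, the estimation choices, and the places where the
design was genuinely open.

## Data model

The unit of analysis is the area–period cell of a complete panel:
counts `y_it`, populations `P_it`, and covariates `x_itk` over `n` areas
and `T` contiguous yearly periods. Static covariates (one value per
area) are broadcast over periods. Holes in the panel are a hard error —
the models assume a complete rectangular layout and no imputation is
attempted.

Counts are modelled as

    y_it ~ Poisson(E_it * exp(eta_it))

with internally standardized expected counts `E_it = P_it * (Σy / ΣP)`
as offset. This makes `exp` of every linear-predictor component a
relative risk against the study-wide average, and guarantees
`Σ E = Σ y` exactly. An explicit offset matrix can be supplied instead
(externally standardized `E`, or unit offsets for calibration studies).

## Model families

All families share the BYM convolution `u_i + v_i`: a spatially
structured intrinsic-CAR effect `u` (precision matrix `Q = D − A` over
the queen-contiguity graph) plus an exchangeable effect `v`.

- `null_parametric` — intercept, grand linear time slope `gamma`,
  area-specific differential slopes `delta_i` (exchangeable, sum-to-zero),
  BYM effects. No covariates.
- `model1a` — adds linear covariate effects `beta_k x_itk`.
- `model1b` — as 1a but a declared subset of covariates is smoothed by a
  second-order random walk `f_k` over binned covariate values; the time
  trend stays linear (with the differential component).
- `null_dynamic` / `model2` — the linear trend is replaced by a
  non-parametric dynamic one, `phi_t + psi_t`: an RW2 period effect plus
  an exchangeable period effect. Covariates in `model2` are all linear.

Time is centred at the middle period, so `exp(gamma)` is the relative
risk per year around the study midpoint. Population density enters on
the natural-log scale; all other covariates in their raw units
(EUR 1,000 for income, percentage points, providers per 100,000), so
coefficients are per-unit log relative risks.

### RW2 covariate effects

An RW2-smoothed covariate is discretized onto `m` equally spaced bins
spanning its observed range (default `m = 100`); each observation maps
to its bin and the curve `exp(f_k)` is reported at bin midpoints with
pointwise credibility intervals and per-bin observation counts. Values
outside the binning range (possible when a binning built on one panel is
applied to another) are clamped to the boundary bin with a warning.

### GMRF structures and scaling

ICAR, RW2 and iid structures are represented by their (possibly
rank-deficient) precision structure matrix `Q`, the declared rank
deficiency, and identifying sum-to-zero constraints (one per connected
component for ICAR, where an island's constraint degenerates to the
point constraint `u_island = 0`; one for RW2, whose null space also
contains the linear trend).

Every intrinsic structure is *scaled* before use: `Q` is multiplied by
the geometric mean of the marginal variances of its constrained
generalized inverse (computed by dense eigendecomposition, exact at the
few-hundred-node scale areal models live at; degenerate zero-variance
nodes are excluded from the mean). After scaling the geometric-mean
marginal variance is 1, so a single Gamma hyperprior means the same
amount of smoothing regardless of graph topology or bin count, and the
operation is idempotent. Constrained sampling works on the eigenbasis
restricted to positive eigenvalues, which satisfies the identifying
constraints by construction.

## Priors

- Precisions `tau`: Gamma(1, 5e-5) — the vague default conventional in
  disease mapping; individually overridable.
- Intercept, coefficients, grand slope: Normal(0, 1000).

A sensitivity utility refits the model over a grid of hyperprior
settings and reports the maximum absolute log-RR shift per fixed effect.

## Estimation

The posterior is sampled by adaptive Metropolis-within-Gibbs:

- every precision gets a conjugate Gamma update,
  `tau | field ~ Gamma(a + rank/2, b + field' Q field / 2)`;
- every latent coordinate gets a single-site Gaussian random-walk
  Metropolis update with a per-site step size adapted toward 0.44
  acceptance during burn-in (Robbins–Monro on the log step, batch window
  50) and frozen afterwards to preserve ergodicity.

Site updates are executed in conditional-independence batches — colour
classes of the neighbour graph for the ICAR field, indices mod 3 for
RW2 fields (their precision couples indices up to distance 2), all
sites at once for exchangeable fields, whose full conditionals are
independent given the rest. Within a class this is mathematically
identical to a site-by-site sweep and keeps a 15,000-iteration fit of a
400-area panel under half a minute.

Two reparametrizations improve mixing without changing the model:
covariates are centred at their grand mean inside the sampler (the
stored intercept is mapped back to the raw scale), and after each sweep
the sum-to-zero constraints are re-imposed by centring with the removed
means folded into the intercept (or, for the differential slopes, into
the grand slope) so the linear predictor is unchanged. The
unstructured area effect `v` is centred as well — without this the
intercept and the mean of `v` are separated only by their priors. The
linear predictor is recomputed exactly from the centred state at the
end of every sweep, so incremental-update drift cannot accumulate.

Initialization is deterministic: all latent components zero, all
precisions one. A non-finite initial log-posterior or `|eta| > 50` at
any iteration aborts with the iteration index. Chains are reproducible
bit-for-bit given the seed. Reported diagnostics: overall acceptance
rates per block and split-chain potential scale reduction for the
intercept, coefficients and slope.

## Reporting conventions

- Relative risk point estimate: `exp(posterior mean coefficient)`;
  interval: `exp` of the 2.5/97.5 posterior percentiles.
- Per-area residual relative risk: `exp(u_i + v_i)` draw-wise, then
  summarized; differential trend per area: `exp(delta_i)`.
- Non-linear curves: `exp(f_k)` pointwise over bin midpoints.
- DIC with the latent-field focus: `Dbar + pD`, where the plug-in
  deviance is evaluated at the posterior mean linear predictor.

## Exploratory statistics

Moran's I uses the standard cross-product form
`I = (n/S0)(z'Wz)/(z'z)` on row-standardized queen weights; islands
contribute nothing to the numerator but remain in `n`. The bivariate
form normalizes the cross product by both vector norms, so it reduces
exactly to the univariate statistic on identical maps. Permutation
inference reports `(r+1)/(M+1)` with `r` counted on the side of the
observed deviation from `E[I] = −1/(n−1)`; the test is directional
because both clustering and dispersion are one-sided departures. In the
bivariate test only the later map is permuted — the null destroys the
space–time alignment while keeping each map's own distribution.
Spearman screening delegates to scipy's tie-corrected (average-rank)
implementation; a constant covariate yields NaN in its row/column with
a warning.

Queen contiguity is detected by snapping polygon vertices to a
tolerance grid (default 1e-8) and intersecting the snapped point sets —
exact on lattices and robust to coordinate jitter in boundary files. A
T-junction vertex that one polygon does not carry in its own ring is
not detected; boundary files of administrative mosaics carry shared
vertices, and the GAL route is available where they do not.

## Synthetic data

The simulator emulates a national district panel: a `rows x cols`
lattice of unit squares under queen contiguity (default 20 x 20 = 400
areas, matching the order of magnitude of a federal district system)
over 5 yearly periods. Populations are log-normal across areas (median
150,000, log-sd 0.6) and constant over the short study window. Each
covariate is mean + scaled-ICAR spatial field + white noise; the
time-varying ones (income, unemployment, density) evolve as stationary
AR(1) deviations (persistence 0.9–0.98), the four static ones (depression
prevalence, GP/psychiatrist/psychotherapist densities) are one
cross-section broadcast over periods; all are clipped to plausibility
bounds. The default unemployment field (mean 8%, spatial sd 3.5, range
0.5–20%) deliberately carries the strong east–west-style dispersion of
the emulated setting, so a curved effect with a peak near 11% has
populated support on both sides of the peak.

True effects default to the regime the models are built for: per-unit
RRs 0.994 (income), 1.015 (unemployment), 0.959 (log density), 1.008
per year for the grand trend, weak effects for the remaining
covariates; field standard deviations 0.15 (`u`), 0.05 (`v`), 0.005
(`delta`) on the log-risk scale, baseline rate 12 per 100,000
person-years. A `nonlinear` scenario variant replaces the linear
unemployment effect with a rise of 0.02 log-risk per point up to a peak
at 11% and a flat segment beyond, exercising RW2 smoothing. Ground
truth (all latent components, centering constants, offsets and the
exact `eta` matrix) is returned with the panel.

What the simulator does *not* emulate: real administrative geographies
(areas are equal-sized squares with near-homogeneous neighbour counts),
boundary changes, migration, demographic structure, reporting artefacts,
or covariate measurement error. Passing recovery tests therefore show
the estimator is correct under the model's own assumptions at realistic
sizes and effect magnitudes — not that those assumptions hold in any
particular registry dataset.

## Numerical choices

- Eigenvalues below `1e-9 * max(lambda, 1)` count as the null space; the
  declared rank deficiency is checked against it.
- Scaled structures hit geometric-mean marginal variance 1 within 1e-6.
- Constraint residuals of stored draws are below 1e-8.
- Result tables serialize floats at 17 significant digits, so write/read
  round-trips are exact to better than 1e-12 relative.
- Degenerate inputs fail loudly: constant vectors in Moran statistics,
  all-zero count panels, non-positive populations, non-contiguous
  periods, asymmetric weights.

## Problem sizes in the test suite

The statistical acceptance checks run at the sizes the method targets
while staying desk-scale: parameter recovery uses ten replicate
20x20 x 5 panels with 15,000-iteration chains; DIC ranking uses ten
seeds per comparison with 4,000-iteration chains (DIC point estimates
stabilize well before the effect summaries do); curve recovery uses 30
bins and an 8,000-iteration chain; the intercept-only quadrature
comparison uses 20,000 retained draws. The pipeline smoke
configurations use 5x5 lattices.

## Known limitations

- The sampler is single-site; for fields with very strong posterior
  coupling (e.g. extreme smoothing) block updates would mix faster.
- DIC is the only fit criterion, chosen for comparability with standard
  disease-mapping practice; WAIC/LOO are out of scope.
- The dynamic-trend families need at least 3 periods (RW2 support).
- The differential slopes `delta_i` are exchangeable; a spatially
  structured alternative would be a one-line change of structure but is
  not exposed.
- Moran's I inference is permutation-based only; analytical moments
  under normality are not implemented.
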