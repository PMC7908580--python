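# Methods

This note documents the models, algorithms and numerical choices behind
`maupmtup`, and what the synthetic data do and do not establish.

## Synthetic study system

The generator emulates a semi-arid agricultural region observed over a
15.5-year study period (2002-01-01 to 2017-06-30 by default), with rainfall
available from 30 months before the study so that every exposure window
(up to 24 months of lag plus 6 months of length) is covered.

**Geography.** Base spatial units are the cells of an `n_rows x n_cols`
rook-adjacency rectangular lattice — the simplest connected planar graph
with controllable size. Real geographies can be supplied instead through
the adjacency/population CSV readers in `maupmtup.io`. Units carry
gender-stratified populations at three census nights (2006, 2011, 2016);
census-1 unit totals are uniform on a configurable range (default 100–320,
giving a 30x30 default region of roughly 190,000 residents), split
binomially between genders, and drifted by ±10% per intercensal period.
Populations at arbitrary dates come from piecewise-linear interpolation
between censuses (linear extrapolation outside, floored at zero), evaluated
at the outcome window's midpoint — the midpoint is a symmetric person-time
proxy; the evaluation time point within the window is a free design choice.

**Rainfall.** Daily rainfall lives on a grid coarser than the unit lattice
(cells cover `grid_factor²` units; for `grid_factor > 1` the grid is offset
half a unit so border units straddle cells and exercise the area-weighted
mapping). The deterministic annual cycle is a sinusoid peaking mid-July and
troughing mid-January, calibrated so the June–August and December–February
daily means equal the configured winter (1.50 mm) and summer (0.43 mm)
targets exactly; amplitude calibration divides by the mean of the cosine
over the winter window rather than assuming the window sits entirely at the
peak. Stochastic structure has two parts: a mean-one log-normal anomaly per
calendar month shared across the grid (default log-SD 0.25, producing the
large interannual swings characteristic of such regions) and additive
Gaussian cell-day noise truncated at zero (default SD 0.5 mm). The
truncation slightly inflates means when the noise SD is large relative to
the seasonal mean; noise-free runs reproduce the configured seasonal means
to well within ±0.1 mm. The marginal daily distribution is *not* a
realistic rainfall distribution (no dry-day point mass, no skew); it is a
stand-in sufficient for testing the pipeline's contracts, not a weather
generator. Spatial autocorrelation beyond the shared monthly anomaly is
not modelled.

**Events.** Counts follow the same process the model assumes:
`y_iw ~ Poisson(e_iw · exp(α + β·x_iw + u_i + v_i))` with `e_iw` equal to
the unit's interpolated population times a base rate (default 0.02 events
per person per 12-month window, matching an annual rate of ~20 per 1000).
`u` is an exact ICAR draw (see below), `v` IID normal; one `(u, v)`
realization per replicate, shared across windows, because the model indexes
random effects by area only. The truth exposure `x` is configurable:
`winter` applies β to the most recent complete June–August mean rainfall
before each window's end (used for the qualitative-signature experiments),
`arrangement` uses each preparation's own paired rainfall covariate, and
`none` sets the exposure effect to zero.

**ICAR simulation.** Draws are taken in the span of the non-null
eigenvectors of the graph Laplacian with variance `σ_u²/λ_k` along
eigenvector `k`; this is the proper distribution obtained by constraining
the intrinsic CAR to sum to zero, so the constraint holds exactly (to
1e-9) by construction. A dense eigendecomposition is used; it is performed
once per graph and is comfortably fast for the lattice sizes here (≤ ~2000
nodes).

## Zone design

The builder is an AZP-style (automated zoning procedure) aggregator with
the squared-deviation objective `Σ_z (pop_z − target)²`:

1. seed `round(total_pop/target)` zones at distinct random units;
2. grow regions by repeatedly attaching the (zone, unassigned neighbour)
   pair whose attachment least increases the objective;
3. refine by single-unit boundary moves that strictly reduce the objective,
   skipping moves that would disconnect or empty the donor zone, sweeping
   until no improving move remains (a local optimum under single-unit
   moves — verified by an exhaustive boundary sweep in the tests).

Ties are broken by lowest unit identifier, so results are a deterministic
function of the seed. No compactness/shape penalty is applied. Zonations
are built once from the final-census total (both-gender) populations and
reused for all windows and both genders; gender stratification therefore
halves effective zone populations downstream, which is intentional. The
default zonation system is the identity (base-unit) zonation plus five
replicate aggregations at each of five population targets (500–7500): 26
zonations.

## Temporal windows

Outcome windows are 12 calendar months ending on the last day of one of
six endpoint months (February, April, June, August, October, December),
enumerated yearly and kept only when both endpoints lie inside the study
period. Exposure windows span 3 or 6 whole calendar months and end exactly
`lag ∈ {0, 6, 12, 18, 24}` months before the outcome window's end month —
lag 0 means the exposure window abuts the outcome window's end. Month-level
closed intervals are used throughout. Note a calendar consequence of the
inclusion rule: over the default study period the August and October
endpoints admit 14 windows (their first candidate window starts in 2001)
while the other four endpoints admit 15.

## Data preparation

Gridded rainfall maps to units by the overlap-weight convex combination
(area-weighted average). Zone events and populations are sums over
comprised units; zone daily rainfall is the *unweighted* mean across
comprised units (not population- or area-weighted), averaged over the
exposure interval to give the covariate in mm/day. Expected counts are
computed within each prepared dataset (one gender, one arrangement, all
windows pooled) as `e = pop · Σy/Σpop`, making θ a standardized incidence
ratio and forcing `Σe = Σy`; a per-window variant is available as a
sensitivity option (`BYMConfig.per_window_expected`).

## BYM sampler

Metropolis-within-Gibbs with the following blocks per sweep:

* `α`, `β`: scalar adaptive random-walk Metropolis against the full Poisson
  likelihood. The covariate is centred internally (`x − x̄`) to decorrelate
  the two blocks; the reported intercept is transformed back.
* `u`: single-site random-walk updates vectorized over graph-colouring
  classes of the zone graph (no two adjacent zones updated simultaneously,
  so the parallel accept/reject within a class is a valid Gibbs scan). The
  ICAR full conditional contributes `n_i (u_i − ū_δi)² / 2σ_u²`. After each
  sweep `u` is re-centred to sum to zero with the offset absorbed into `α`
  — the standard identifiability fix, exact up to the (vague) intercept
  prior. Zones without neighbours (possible in degenerate aggregations)
  have `u` fixed at 0; if islands coexist with a connected block the
  centring of that block cannot be absorbed into a single intercept and is
  applied as the usual small approximation.
* `v`: single-site random-walk updates, all zones in parallel (their full
  conditionals are mutually independent given the rest).
* `σ_v²`, `σ_u²`: conjugate inverse-gamma draws. The ICAR quadratic form is
  `Σ_{i~j}(u_i − u_j)²` over unordered neighbour pairs with degrees of
  freedom `n − c`, `c` the number of connected components of the zone
  graph (shape/rate parameterization throughout).

Step sizes adapt in batches of 50 iterations during burn-in toward a 0.44
acceptance rate (the scalar random-walk optimum) and are frozen afterwards;
acceptance rates outside [0.05, 0.95] after burn-in trigger a warning
carrying the chain diagnostics. Defaults: 2 chains, 4000 iterations, 2000
burn-in, thinning 2. Per-zone likelihood contributions multiply over that
zone's (up to 15) window rows, with `u_i, v_i` shared across windows; rows
with zero population are dropped (counted in the diagnostics).

Numerical notes: a replicate-heavy validation (coverage studies) uses a
shortened single-chain configuration (2000 iterations, 800 burn-in) chosen
to keep whole-suite runtimes modest; the rainfall coefficient β typically
has effective sample sizes in the hundreds even at that length. The two
variance components are only weakly separated by the data (a well-known
BYM identifiability weakness) and mix slowly; they are nuisance parameters
here and their posteriors should not be over-interpreted. Variances are
floored at 1e-12 to avoid division underflow in near-degenerate fits.

## Rate ratios and consistency classification

Each β sample is transformed to `exp(β·s)` with `s = 0.5` mm by default
(the scale of the interannual SD of seasonal daily rainfall); the estimate
is the posterior mean with an equal-tailed 95% credible interval. For one
temporal arrangement and gender, the estimates across zonations are
classified:

* **inconsistent** if any interval contains 1 *or* any two point estimates
  lie on opposite sides of 1 (an RR exactly 1.0 necessarily has an interval
  containing 1, hence inconsistent — the edge rule);
* otherwise **consistently positive** (all RRs > 1) or **consistently
  negative** (all RRs < 1).

The grid cell's shade is the arithmetic mean of the posterior-mean RRs
(not the mean of log-RRs).

## Validation design and problem sizes

* *GLM-oracle equivalence*: with negligible random-effect variances the
  model collapses to a Poisson GLM with offset; the posterior mean of β is
  checked against an independent IRLS fit (statsmodels) on 150 zones × 15
  windows.
* *Null coverage / parameter recovery*: 50 (respectively 40) replicate
  datasets at 150 zones × 15 windows, β = 0 (respectively 0.1 per mm),
  σ_u² = σ_v² = 0.05; interval coverage and posterior-mean bias are checked
  against binomial tolerances.
* *Qualitative signature*: a 5×5-unit region observed over a 39-year
  synthetic period with a strong negative winter-rainfall effect
  (β = −0.4 per mm). The long period gives each arrangement ~39 windows,
  which shrinks the chance correlation between winter and summer rainfall
  series enough that arrangements measuring summer rainfall reliably stay
  inconsistent while the two winter-matched arrangements (August endpoint
  with lag 0; February endpoint with lag 6) are consistently negative
  across all zonations. Counts are kept low (≈3 expected events per
  unit-window) so that exposure-mismatched arrangements are not powered
  into spurious consistency by temporal confounding the model does not
  represent.

What passing these checks shows: the sampler targets the right posterior,
the preparation algebra conserves events and population exactly, and the
full pipeline recovers a known spatiotemporal signature. What they do not
show: anything about real rainfall marginals, real geographies, migration
or age structure, or the magnitude of MAUP/MTUP variability in any real
dataset — the generator is deliberately simpler than nature on all those
axes.

## Known limitations

* The ICAR re-centring with islands present is approximate (see above).
* No temporal random effect: year-to-year outcome variation not explained
  by the exposure inflates apparent precision; in null settings this is
  visible as occasional credible intervals that exclude 1. The real
  analysis this mirrors shares the limitation by design.
* Whether the inverse-gamma hyperpriors are shape/rate or shape/scale is
  ambiguous in common notation; shape/rate on the variances is used.
* The expected-count construction (internal indirect standardization,
  pooled across windows) is one defensible choice among several; the
  per-window option quantifies its influence.
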