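# Methods

This note documents the statistical models the package implements, the
choices made where the design was open, and what the synthetic-data tests
do and do not demonstrate.

## Distance sampling

Observed perpendicular distances on `[0, w]` follow `f(x) = g(x)/μ` with
`μ = ∫₀ʷ g`. Three detection families are fitted by maximizing
`Σ log f(x_i)`:

* **uniform** — `g ≡ 1`, no free parameters, `μ = w`,
  `loglik = −n log w` in closed form;
* **half-normal** — `g(x) = exp(−x²/2σ²)`, one parameter;
* **hazard-rate** — `g(x) = 1 − exp(−(x/σ)^(−b))`, two parameters with
  `b > 1` enforced (the density is not integrable near the origin
  otherwise).

Optimization is bounded L-BFGS-B on log-parameters with five start points;
the hazard-rate likelihood is multimodal and the multistart guards against
local optima. `μ` is evaluated by adaptive quadrature; its CV comes from
the delta method using a finite-difference observed information matrix
(uniform: CV = 0). Model choice is minimum AIC, ties broken toward fewer
parameters. The truncation distance defaults to the maximum observed
distance; no series adjustments (cosine/polynomial) are offered — only the
three base families. One pooled detection function is fitted per survey
epoch; per-location detection is out of scope.

## Density and change inference

Transects within a sampling location pool into independent units
(`l_i = Σ` lengths, `n_i = Σ` counts). The encounter-rate variance is the
classical effort-weighted between-unit estimator

    var(n/L) = k / (L² (k−1)) · Σ l_i² (n_i/l_i − n/L)²,

and `CV(D)² = CV(n/L)² + CV(μ)²`. Intervals are log-normal,
`(D/C, D·C)` with `C = exp(z_{α/2} √(ln(1+CV²)))`, using the standard
normal critical value (1.96 at 95%): with ~50 units the difference from a
Satterthwaite-t interval is negligible and the plain-normal form
reproduces summary-report intervals to ≤0.02 per ha.

The two-survey test is `z = (D₁−D₂)/√(SE₁²+SE₂²)`; the p-value is
one-sided (upper tail) by default, two-sided by flag. Per-location changes
are classified with a "same" tolerance ε (default 0.1 in the density unit
supplied, configurable — the unit convention of the reported 0.1 threshold
is ambiguous between per-ha and per-km² in survey practice, so it is a
parameter, not a constant). The three class counts are tested against
equal expected frequencies with a df-2 chi-square.

Dung-to-elephant conversion is `E = D/(T·r)` with survival time `T = 44`
days and defecation rate `r = 19.77` piles/day as defaults; both are taken
as given inputs — the package does not model decay. Population
extrapolation deliberately rounds the density to 2 decimals before
multiplying by the area, matching the convention of reported headline
figures. Note `23687 kg / 6.9 kg` is exactly 3433.0; the ivory conversion
returns 3433 (some published roundings give 3434).

## Kriging and hotspots

The empirical semivariogram uses 12 bins to half the maximum pairwise
distance by default; spherical (default) or exponential models are fitted
by least squares weighted by √(pair count), with non-negativity bounds; a
range pinned at a bound is flagged degenerate. Ordinary kriging solves the
semivariance system with a Lagrange unbiasedness row at every node, so
weights always sum to one and the predictor is exact at data points when
the nugget is zero. Duplicate data points are averaged (or rejected, per
configuration). No declustering, anisotropy, or universal/co-kriging.

Gi\* uses binary distance-band weights including the self term, with the
band defaulting to twice the median nearest-neighbour distance; z-scores
standardize the local weighted sum against the global mean and population
SD, and |z| > 1.96 flags hot/cold spots (no multiplicity correction —
flags are per-location decisions at the 5% level).

## Density-surface GAMs

Counts per transect are modelled with a log link and offset
`log(2 μ̂ l_i)` — the effective area surveyed — so the linear predictor is
log density. Smooths are cubic B-splines with knots at covariate
quantiles, basis dimension k = 5 by default (with ~50–110 units a larger
basis saturates), identified by absorbing the sum-to-zero constraint into
the basis; the penalty is the exact integrated squared second derivative
(2-point Gauss per knot interval), whose null space makes a fully
penalized smooth collapse to a straight line (term edf → 1 beyond the
intercept). Fitting is penalized IRLS on the Poisson estimating equations;
overdispersion is quasipoisson, `φ = Pearson χ²/(n − edf)`.

Smoothing parameters minimize the Craven–Wahba GCV score
`n·D/(n − edf)²` (γ = 1) by a coordinate grid search over log λ followed
by a Nelder–Mead polish; equivalence with any particular mgcv release is
explicitly not promised — recovery is validated property-wise on
synthetic data. Backward deletion refits every single-term deletion (with
GCV-selected smoothing) and accepts the best one when its GCV is no worse
than the current model's by more than ~2/n relative — the ΔAIC < 2
parsimony rule translated to the GCV scale via AIC ≈ n log GCV; a strict
improvement rule would never remove a term that GCV has already flattened
to edf ≈ 0, since deletion then ties. Term significance against the null
model uses a φ-scaled F test on the deviance reduction. Habitat enters as
per-class indicator (or slope) linear terms.

## Synthetic study design

The generator emulates a two-epoch dung survey of a large forest reserve:
a 130 × 105.4 km park (13,702 km²), a national road bisecting the southern
half plus roads along the east and west, villages within 5 km of roads,
four towns outside the boundary, headquarters at the centre of the main
road, and a 10-km deforestation grid over a 15-km buffer in which clearing
concentrates around the towns (with a minor road-side component) and grows
between the two mapping epochs. 51 sampling locations hold 1–4 transects
of 2.5–5 km (≈110 transects), revisited identically in both epochs.

True log density is linear in distance-to-headquarters (β = −0.5 per
50 km), distance-to-boundary (β = +0.4 per 30 km) and the park-mean-
normalized deforestation index (β = −0.6), with the intercept calibrated
so the epoch-1 park-average density is 4 piles/ha; epoch 2 multiplies the
surface by the decline factor (default 0.5), optionally softened by a
refuge multiplier within a radius of headquarters (default multiplier 1 —
no refuge — so the default scenario realizes the stated 50% decline
exactly; refuge > 1 is used by the hotspot-enrichment tests). Counts are
negative binomial with variance φ·mean (φ = 2), matching the quasipoisson
mean–variance assumption so the GAM's dispersion is estimable; each pile
receives a uniform distance on `[0, w_sim]` (w_sim = 10 m) thinned by the
detection function (half-normal σ = 2 m by default, chosen so simulated
effective strip widths land on the ~2–2.5 m scale typical of dense-forest
dung surveys). A truth ledger records per-transect true densities and
expectations and the park-integrated total, sufficient to recompute every
expectation independently. All randomness derives from
`SeedSequence([seed, stream])`, so equal seeds give byte-identical
datasets, and transect geometry is drawn from an epoch-independent stream.

What the generator does *not* emulate: elephant movement, dung
accumulation/decay dynamics (steady state is simulated directly),
geographic coordinates (planar km throughout), detection heterogeneity
between observers, and the patchy ecozone structure of real habitat (slope
and habitat classes are simple spatial fields). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to these real-data complications.

## Problem sizes in the test suite

Simulation-based tests use the default design (51 locations, ~110
transects): 50 replicates for the GAM sign/ranking recovery study, 200
replicates for the end-to-end decline recovery and power check, 500
replicates for interval coverage, 10,000 draws for the chi-square type-I
rate. Oracle-equality checks (kriging solve, Gi\*, de Boor basis,
semivariogram) run on ≤40-point fixtures at tolerances 1e-8–1e-12.

## Numerical details and edge cases

* Detection fits require ≥10 in-range distances (configurable) and raise
  typed errors otherwise; non-convergent IRLS raises with its deviance
  trace.
* The deforestation index floors cell distances at half a cell size to
  avoid the singularity at a cell centre; the index is additive over grid
  partitions and 1/d-homogeneous away from the floor.
* Constant covariates are rejected in smooths and dropped (with a warning)
  by the collinearity screen, which retains the higher-priority member of
  any pair with |Pearson r| ≥ 0.6, visiting covariates in a fixed priority
  order (roads, villages, towns, boundary, headquarters, deforestation
  index, slope, habitat).
* Kriging variances are clipped at zero against round-off; a constant
  field makes Gi\* undefined (zero variance) and raises.
* Densities are reported per hectare with metre ESWs and km efforts
  (1 m·km = 0.1 ha); the GAM offset inherits the same convention, where
  unit changes shift only the intercept.
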