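# Methods

## Model

The package treats two misaligned areal data sources as aggregates of one
spatially continuous, zero-mean Gaussian process U(x) with exponential
covariance `tau^2 exp(-||x-x'||/delta)` (distances Euclidean, metres). The
observation model is

    Y_ij = alpha_i + beta_i * Ubar_j + T_ij      i = 1, 2 (groups), j coarse units
    Z_k  = gamma + Ubar*_k + V_k                 k fine units

with `Ubar_j`, `Ubar*_k` polygon averages of U, `V_k ~ N(0, nu^2)` i.i.d.,
and `(T_1j, T_2j)` i.i.d. bivariate normal with covariance Omega. The
covariate is modelled on its own scale (gamma absorbs its mean); the outcome
loads on the *same* latent surface through group-specific slopes beta_i, so
Cov(Y_ij, Z_k) = beta_i * tau^2 * fbar(coarse_j, fine_k; delta), where fbar is
the area-normalised double integral of the kernel over the two polygons.

Key assumptions: a single shared spatial process carries *all* spatial
structure in both variables (checked post hoc by the variogram diagnostic);
stationarity and isotropy of U; Gaussian noise at the unit level; no missing
values.

## Areal integrals and quadrature

All polygon integrals are approximated on a regular lattice of cell centres:
fbar(A, B; delta) is the mean of `exp(-d/delta)` over all pairs of lattice
points assigned to A and B, and the point-to-polygon covariance is the
analogous single mean. Points are assigned by point-in-polygon with a
first-wins rule on shared boundaries so each partition stays disjoint; every
unit must capture at least one point (error otherwise; warning below four).
Multi-part polygons are handled as the union of their parts.

The default lattice spacing is 150 m for a city-scale (~10 km) domain, the
same resolution used for simulation; predictions default to a 250 m lattice.
The within-unit (diagonal) factors are the quantity most sensitive to
spacing: on desk-scale tessellations a 500 m lattice overstates the
within-fine-unit mean correlation by about 0.035, which at tau^2 ~ 500 is
larger than the entire nugget nu^2 ~ 13 and visibly biases the fit (nu2_hat
collapses to zero). Fitting therefore uses the same lattice that defines the
aggregation wherever possible.

Because likelihood maximisation re-evaluates every unit-pair factor at each
candidate delta, the `FactorTable` pre-accumulates pairwise-distance
summaries once: exact integer displacement classes on small grids (an exact
regrouping of the pairwise mean), and, on large grids, distance bins of
width spacing/2 storing per-(pair, bin) counts and first moments. Bin
evaluation applies a first-moment correction around the bin centre, leaving
a second-order error `<= (h/(2 delta))^2 / 2` per entry — measured at most
2.4e-3 relative on the 150 m desk grid at delta = 400 m, and 1.3e-4 at the
default delta. The optimiser's lower bound delta >= spacing/2 both reflects
identifiability (ranges below the grid resolution cannot be resolved) and
keeps the binned correction positive.

Quadrature-approximated kernels can be numerically indefinite, so every
covariance matrix receives a relative diagonal jitter of 1e-8 before
factorisation.

## Likelihood and fitting

The exact Gaussian log-likelihood is evaluated through the factorisation
`[Y1, Y2, Z] = [Y1, Y2 | Z] [Z]`; the conditional uses the full covariate
covariance `Sigma_fine + nu^2 I` (the only form for which the factorisation
reproduces the stacked joint density, which the test suite verifies to 1e-6
relative on random instances).

Parameters are optimised on an unconstrained scale: log tau^2, log delta,
log nu^2, log omega_1^2, log omega_2^2, and atanh of the cross-group noise
correlation rho = omega_12/(omega_1 omega_2). The atanh parameterisation
keeps Omega positive definite and — unlike a log omega_12 scale — admits
negative cross-covariance; a delta-method log(omega_12) row is added to the
report when rho_hat > 0, matching the conventional reporting scale. The
intercepts (alpha_1, alpha_2, gamma) enter only the mean and are profiled
out by generalised least squares at each covariance evaluation, reducing the
search to 8 dimensions (6 for the no-covariate variant, which fixes
beta_1 = beta_2 = 0).

Initial values are method-of-moments: sample means for the intercepts and
gamma; an even split of the covariate variance between tau^2 and nu^2;
delta at a quarter of the domain diameter; beta and Omega from ordinary
least squares of the outcome on the quadrature-averaged covariate. L-BFGS-B
with numerical gradients runs from this start plus (by default) four
perturbed restarts; box bounds keep the search off degenerate ridges.
Convergence tolerance is 1e-9 on the relative objective. Wald 95% intervals
come from the inverse observed information (central finite-difference
Hessian on the transformed scale). Fewer than 3 units per partition or a
constant covariate are rejected as unidentifiable.

At small m the nugget nu^2 is weakly identified against the smooth field and
its MLE sits at the zero boundary in roughly a quarter of desk-scale
replicates; this is the genuine global optimum (verified by multi-start and
truth-initialised runs), not an optimiser artefact, and it is the main
driver of plug-in prediction-interval undercoverage discussed below.

## Prediction

The target surface for group i is `Y_i(x) = alpha_i + beta_i U(x)`, the
de-noised outcome. All cross-covariances between targets and observations
are derived from the single joint model, e.g.
`Cov{Y_i(x), Y_i'j} = beta_i beta_i' tau^2 kbar(x, coarse_j)` with kbar the
area-normalised point-to-polygon kernel mean — the forms implied by the
model definition, verified against a one-unit analytic conditional and
simulation oracles. Prediction is the plug-in Gaussian conditional at the
MLEs; parameter uncertainty is deliberately ignored, and the coverage study
quantifies the cost of that choice. Conditioning defaults to the full data
(outcome and covariate); a `leb_only` flag conditions on the outcome alone.

Non-exceedance probabilities `NEP_i(x) = Pr(Y_i(x) < l | data)` are computed
in closed form from the Gaussian marginals (degenerate marginals resolve to
0/1, and 0.5 exactly at the threshold); classification uses NEP >= 0.8 for
"likely below", <= 0.2 for "likely above", in between "uncertain".

Unit-level ("areal") prediction offers two targets: the noise-free
aggregated surface `alpha_i + beta_i Ubar_j` (default; the quantity mapped
as a model-based unit estimate) and, with `include_noise=True`, the
observable unit-level outcome, whose predictive variance adds omega_i^2.
The coverage study uses the second, since a "prediction interval for the
unit-level outcome" refers to where a published (noisy) unit figure would
fall; with the noise-free target the conditional sd (~0.35 y at desk scale)
is comparable to the plug-in mean error and nominal coverage is unattainable
for any sample size we examined.

## Variogram validation

Residuals `T_hat_ij = Y_ij - alpha_hat_i - beta_hat_i Uhat_j` (Uhat the
conditional mean of the latent areal average given all data) are paired with
area-weighted polygon centroids. The empirical semivariogram uses 12 equal
distance bins on [0, 10] km by default (upper edge falls back to half the
centroid-cloud diameter on smaller domains); empty bins are reported as
missing, not zero. The tolerance envelope permutes the residual-to-centroid
assignment B times (default 1000, minimum 100) and takes pointwise 2.5%/97.5%
quantiles per bin; the verdict is "inside" iff every non-empty bin's observed
value lies within its band.

The envelopes are pointwise and deliberately uncorrected for multiplicity,
matching standard practice for this diagnostic. Consequence: under a
correctly specified model the *family-wise* "all 12 bins inside" event
occurs in only ~50-55% of runs (~0.95^12), even though each bin individually
holds its 5% level — users should read excursions bin-wise, and treat an
isolated single-bin excursion as unremarkable. Power is good: a smooth
spatial trend of 1.5x the noise sd is flagged in essentially every run.

## Synthetic data and the coverage study

The generator tiles a rectangle (default 10 km square) with two independent
tessellations — Voronoi cells of uniform seeds with two Lloyd-relaxation
rounds (administrative units are roughly size-balanced, and relaxation
guarantees each cell captures lattice points), or rectangular blocks — and
simulates U exactly by dense Cholesky factorisation on the 150 m lattice
(grids above 8000 points are refused; at desk scale exactness simplifies
oracle testing and the factor is cached across replicates). Aggregation uses
the same lattice, so the simulated data's covariance is exactly the model's.

Default true parameters are the fitted values from the motivating urban
analysis (alpha = (75.47, 81.12) years, beta = (-0.154, -0.129),
gamma = 39.2, tau^2 = e^6.226, nu^2 = e^2.586, omega_1^2 = e^1.810,
omega_2^2 = e^2.581, omega_12 = e^1.671), with delta = e^7.336 rescaled in
proportion to the domain diagonal (reference diagonal 13 km) so the
correlation range occupies the same fraction of the synthetic domain.

The coverage study simulates B datasets (default 200 at desk scale, 30
coarse / 90 fine cells), refits each by maximum likelihood (single start
from the method-of-moments initialisation), and records, at nominal levels
0.05..0.95: Wald-interval coverage for beta_1 and beta_2; prediction-interval
coverage for the observable unit-level outcome; and prediction-interval
coverage for the continuous surface on a fixed seeded subsample of the
simulation lattice (cap 1200 points — an unbiased estimate of the
grid-average coverage at a fraction of the cost). Failed fits are logged and
excluded with a reported count; a single seed drives everything, so results
are bit-reproducible.

What the study shows at desk scale: beta intervals and unit-outcome
prediction intervals are essentially nominal at every level; intervals built
from the *true* parameters are exactly calibrated (confirming the
conditional algebra); but plug-in continuous-surface intervals undercover at
the highest levels (~0.88 actual at 0.95 nominal), a real cost of ignoring
parameter uncertainty — chiefly the boundary nu2 fits — that shrinks with
the number of units (~0.91 at double the units) but does not vanish.

## What the generator does not emulate

Real administrative geographies have population-weighted centroids, highly
variable unit sizes and population-driven (not uniform) boundaries; real LEB
estimates carry age-structure artefacts and spatially varying sampling error
(the model's constant Omega); deprivation scores are bounded and skewed
rather than Gaussian. Passing tests therefore demonstrate correctness of the
algebra, the estimator and the stated operating characteristics under the
model, not robustness to these departures.

## Known limitations

- Likelihood evaluation is dense (O((2n+m)^3) per step); hundreds of units
  are comfortable, tens of thousands are not.
- Plug-in prediction understates uncertainty where the data are weakly
  informative about the covariance parameters (see the coverage discussion).
- (tau^2, delta) are only jointly weakly identified on domains comparable to
  the practical range — a known exponential-kernel pathology; multi-start
  optimisation and bounds mitigate but cannot remove it.
- One shared spatial process: outcome spatial structure not attributable to
  the covariate is pushed into the unit-level noise. The variogram check
  detects leftover structure but the model cannot absorb it.
- Boundary I/O is GeoJSON-only, planar metric coordinates required.
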