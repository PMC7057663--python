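# arealgp

Model-based geostatistics for **spatially misaligned areal data**: a joint
Gaussian-process treatment of an outcome published as averages over one set of
polygons and a covariate published as averages over a *different, non-nested*
set of polygons covering the same region.

The motivating setting is small-area public health: life expectancy at birth
(LEB) is released by middle-layer census units, while the index of multiple
deprivation (IMD) is released by smaller, misaligned units. Re-aggregating one
variable onto the other's geography discards within-unit variation and biases
both the regression coefficient and its standard error. `arealgp` instead
models both data sources as aggregates of one spatially continuous process,
which also makes *spatially continuous* prediction possible from purely
areal inputs.

## The model

Let $U(x)$ be a stationary Gaussian process with exponential covariance

$$\mathrm{Cov}\{U(x),U(x')\}=\tau^2\exp\{-\lVert x-x'\rVert/\delta\},$$

and let $\bar U_j$ and $\bar U^*_k$ denote its averages over coarse unit $j$
and fine unit $k$. With $Y_{ij}$ the outcome for group $i\in\{1,2\}$ (e.g.
male/female) in coarse unit $j$ and $Z_k$ the covariate in fine unit $k$:

$$Y_{ij}=\alpha_i+\beta_i\,\bar U_j+T_{ij},\qquad
  Z_k=\gamma+\bar U^*_k+V_k,$$

where $V_k\sim N(0,\nu^2)$ i.i.d. and $(T_{1j},T_{2j})$ i.i.d. bivariate
normal with covariance $\Omega=\begin{pmatrix}\omega_1^2&\omega_{12}\\
\omega_{12}&\omega_2^2\end{pmatrix}$. Covariances between areal averages are
double integrals of the kernel over polygon pairs, approximated by quadrature
on a regular lattice. Everything observed is jointly Gaussian, so the package
provides:

- **exact maximum likelihood** (factorised as outcome-given-covariate times
  covariate marginal, intercepts profiled out, variances optimised on the log
  scale), with Wald intervals and a likelihood-ratio test of
  $\beta_1=\beta_2=0$;
- **spatially continuous prediction** of $\alpha_i+\beta_i U(x)$ on a lattice,
  with joint sampling and closed-form **non-exceedance probabilities**
  $\mathrm{NEP}_i(x)=\Pr\{Y_i(x)<l\mid\text{data}\}$;
- **variogram validation**: empirical semivariogram of the estimated unit
  residuals with Monte-Carlo permutation tolerance envelopes;
- a **synthetic-data generator** (misaligned Voronoi/grid tessellations, GP
  simulation, aggregation) and an interval **coverage study**;
- a **Chiang life-table** utility for computing LEB from abridged life tables.

## Worked example

Fully synthetic, so it runs anywhere (about 15 s):

```python
import numpy as np
from arealgp import (make_scenario, simulate_dataset, fit_mle, lr_test,
                     fit_report_table, make_prediction_lattice,
                     predictive_distribution, nep, classify_nep,
                     extract_residuals, permutation_envelope)

scenario = make_scenario(seed=0)   # 10 km square, 30 coarse / 90 fine cells
sim = simulate_dataset(scenario, seed=0)
grid = sim.sim_grid

full = fit_mle(sim.data, grid, options={"seed": 0})
reduced = fit_mle(sim.data, grid, variant="no_covariate", options={"seed": 0})
print(fit_report_table(full).round(3).to_string(index=False))
test = lr_test(full, reduced)
print(f"LR test of beta1=beta2=0: statistic={test.statistic:.1f}, p={test.pvalue:.2e}")

lattice = make_prediction_lattice(scenario.coarse_units, spacing=250)
field = predictive_distribution(full, sim.data, grid, lattice, full_cov=False)
p1 = nep(field, 1, 79.2)
labels = classify_nep(p1)
print(f"group-1 NEP(79.2): mean={p1.mean():.2f}, "
      f"likely_below={np.mean(labels=='likely_below'):.0%}")

res = extract_residuals(full, sim.data, grid)
env = permutation_envelope(res, group=1, B=1000, seed=0)
print("variogram verdict:", "inside" if env.inside else "outside")
```

Output:

```
     parameter  estimate  ci_low  ci_high
       alpha_1    76.013  73.545   78.482
       alpha_2    80.756  78.324   83.188
        beta_1    -0.148  -0.211   -0.086
        beta_2    -0.130  -0.213   -0.046
 log_omega1_sq     2.205   1.695    2.716
 log_omega2_sq     2.790   2.281    3.299
     atanh_rho     0.768   0.408    1.128
         gamma    37.537  22.652   52.422
      log_tau2     6.204   5.649    6.759
     log_delta     7.586   6.659    8.513
       log_nu2     1.616  -3.745    6.978
   log_omega12     2.061   1.395    2.726
log_likelihood  -492.625     NaN      NaN
LR test of beta1=beta2=0: statistic=16.4, p=2.74e-04
group-1 NEP(79.2): mean=0.77, likely_below=65%
variogram verdict: inside
```

The data were generated with $\beta=(-0.154,-0.129)$; both coefficients are
recovered inside their 95% intervals, the likelihood-ratio test firmly
rejects "no association", and the residual variogram sits inside its
permutation envelope (no unexplained spatial structure). The NEP column says
at how many lattice points the group-1 surface is at least 80% likely to lie
below the 79.2-year threshold.

A `click` CLI wraps the same pipeline for shell use — `arealgp simulate |
fit | predict | validate | coverage`, each driven by a YAML config and a
seed; run `arealgp --help`.

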