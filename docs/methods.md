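# Methods

## Model

`stcar` fits a hierarchical Bayesian Poisson model for areal count panels:
event counts `Y_it` over `n` regions and `Z` periods, with at-risk totals
`N_it` and expected counts `E_it`,

    Y_it ~ Poisson(mu_it),        mu_it = E_it * lambda_it,
    log lambda_it = eta_it
                  = alpha + x_it' beta + u_i + v_i + gamma_t + psi_it.

The relative risk `lambda_it` is the multiplicative deviation of a cell's
intensity from its expected count. Expected counts default to internal
standardization, `E_it = N_it * (sum Y / sum N)`, so `sum E = sum Y` exactly
and `lambda = 1` means "at the panel's overall rate". Person-time or
age-standardized expected counts can be supplied instead via the panel's
`E` column.

Priors (all precisions `tau = 1/sigma^2`):

- `alpha`: improper flat. Identifiability comes entirely from the
  sum-to-zero constraints below.
- `beta`: iid Gaussian, mean 0, precision `1e-3` (wide). Covariates are
  centred and scaled internally before sampling; reported coefficients and
  relative risks are always back-transformed to the original scale.
- `u` (structured spatial): intrinsic CAR over the contiguity graph —
  conditionals `u_i | u_-i ~ N(mean of neighbours, sigma_u^2 / n_i)`;
  structure matrix `R_u = D - W`, rank `n - #components`.
- `v` (unstructured spatial): iid Gaussian. Together `S_i = u_i + v_i` is
  the BYM convolution prior.
- `gamma` (temporal): first-order random walk, structure = second-difference
  matrix, rank `Z - 1`.
- `psi` (space-time interaction), Knorr-Held types with region-major layout
  (all periods of region 0 first):
  - type I: iid, `R = I_{nZ}`;
  - type II: independent RW1 per region, `R = I_n (x) R_rw1`, rank `n(Z-1)`;
  - type III: independent ICAR per period, `R = R_icar (x) I_Z`,
    rank `Z * rank(R_icar)`.
  Type IV (structured in both factors) is not implemented.
- Each active precision: `tau ~ Gamma(shape 1, rate 5e-4)`, mirroring the
  common log-Gamma(1, 5e-4) default on the log-precision scale; configurable
  per block.

Structure matrices are *not* rescaled to unit generalized variance (no
`scale.model` analogue): the unscaled `D - W` form matches the conditional
specification above, at the cost that `tau_u` is not directly comparable
across graphs.

### Identifiability constraints

The intrinsic blocks are rank-deficient, so the model is identified by
sum-to-zero constraints: `sum_i u_i = 0` per connected component,
`sum_t gamma_t = 0`, and for the interaction `sum_t psi_it = 0` per region
(type II) or `sum_i psi_it = 0` per period (type III); type I needs none.
Constraints are enforced by recentring with compensation after every
sampler iteration: removed means are absorbed into `alpha` (and, for
type II/III, first into `u` or `gamma`), leaving the linear predictor
exactly unchanged. On a disconnected graph the residual per-component
offsets of `u` go into `v` instead, because a single intercept cannot
absorb different component levels while keeping `eta` invariant.

Recentring `u` and `gamma` into the flat-prior `alpha` is exactly
measure-preserving (the intrinsic kernels are level-invariant). Moving the
interaction's null-direction means into `u`/`gamma` is the standard
identifiability convention for these models rather than an exact MCMC move;
it fixes the representative of an otherwise aliased decomposition.

## Inference

Posterior sampling is Metropolis-within-Gibbs:

- **Latent fields** (`u`, `v`, `gamma`, `psi`, `alpha`): site-wise adaptive
  random-walk Metropolis, target acceptance 0.44. Site updates are
  vectorized over colour classes of conditionally independent sites (even/
  odd periods for RW1, a greedy graph colouring for ICAR); within a class
  sites share no structure-matrix cross terms and no likelihood cells, so
  simultaneous accept/reject decisions are identical to a sequential scan.
  Local acceptance ratios use the sparse-row form of the quadratic-form
  change, never a full matrix product.
- **beta**: joint random-walk block, target acceptance 0.234 (0.44 when
  there is a single covariate).
- **Precisions**: exact conjugate draws
  `tau | field ~ Gamma(a + rank(R)/2, b + field'R field / 2)`. Using the
  rank, not the dimension, is essential for the intrinsic blocks.
- **Aliased-direction moves.** The likelihood identifies only `u + v`, and
  under type II (III) a common temporal (spatial) curve trades off between
  `gamma` (`u`) and `psi`; likewise a covariate's projection trades off
  between `beta_k` and `psi`. Site-wise Metropolis explores these ridges
  slowly, so each iteration adds exact Gaussian full-conditional redraws of
  (a) the `u`/`v` split given `u + v`, (b) the shared curve between the
  main effect and the interaction, and (c) the shift along
  `(beta_k, psi + d x_k)`. All three are likelihood-invariant conditional
  updates and leave the target unchanged.
- **Collapsed spatial-precision update.** `(log tau_u, log tau_v)` also get
  a joint Metropolis update with the `u`/`v` split integrated out
  analytically (the marginal of `u + v` is diagonal in the eigenbasis of
  `R_u`), which removes the precision/split ridge.
- **Adaptation**: Robbins-Monro on log proposal scales during burn-in only;
  scales are frozen afterwards so the stationary target is exact.

Chains are seeded from independent `SeedSequence` streams spawned from one
mandatory user seed; a fixed configuration reproduces bit-identical draws.
Defaults: 4 chains, 15,000 iterations, 5,000 burn-in, thinning 5.

### Verified sampler properties

The test suite checks the sampler against independent oracles: local
acceptance ratios against dense log-posterior differences; conjugate draws
against the closed-form mean; and the full MCMC against 1-D quadrature of
the exact posterior on an intercept-only one-cell model (Kolmogorov-Smirnov
distance < 0.02 at 20,000 retained draws).

## Posterior products

- Fixed-effect relative risks `exp(beta)` with equal-tailed 95% credible
  intervals (2.5/97.5 percentiles, matching the symmetric intervals these
  analyses report; HPD intervals are not used).
- Area-time relative-risk surfaces: per-draw `lambda_it = exp(eta_it)`,
  summarized cellwise.
- Exceedance probabilities `P(lambda_it > T | data)` as the fraction of
  retained draws above the threshold; default `T = 1`, the hotspot
  criterion.
- DIC with `pD = mean deviance - deviance at the cellwise posterior-mean
  linear predictor` (the plug-in convention INLA reports; the
  "mean of parameters" alternative differs for nonlinear functionals).
- WAIC with the variance penalty
  `-2 sum_it [log mean_s p(Y_it | mu^(s)) - var_s log p(Y_it | mu^(s))]`.
- Model comparison tables sorted by DIC, ties broken by WAIC then by
  smaller `pD`; fits of different panels are refused via a recorded data
  hash. The marginal likelihood is not computed: there is no reliable
  MCMC estimator for it at this effort level.

## Synthetic data

The generator draws every random-effect block from its prior restricted to
the non-null eigenspace of its structure matrix (null directions zeroed),
so simulated truths satisfy the same constraints the fitted model imposes.
Counts are drawn as `Y_it ~ Poisson(N_it * rate * exp(eta_it))`; the
returned panel's `E` is then recomputed by internal standardization from
the simulated counts, exactly as an analysis of real data would.

Two scenarios ship with the package:

- `lattice_scenario`: 4x4 rook lattice, `Z = 8`, one standardized
  "duration on treatment" covariate with true RR 0.651 per SD, at-risk
  1,000 per cell at baseline rate 0.2 (expected counts ~200), type II
  interaction. True precisions `tau_u = 4, tau_v = 10, tau_gamma = 4,
  tau_psi = 4` — moderate spatial/temporal variation (effect SDs 0.3-0.5)
  that is recoverable at this panel size.
- `zimbabwe_scenario`: 10 regions on Zimbabwe's province contiguity,
  `Z = 8`, five programme covariates (female proportion, mean age, TB
  co-infection proportion, WHO stage III/IV proportion, mean years on ART),
  at-risk totals lognormal around 3,000, baseline event rate 0.227. Only
  the duration covariate carries a true effect (RR 0.651 per year); the
  intercept subtracts the covariate-mean contribution and half the average
  prior variance of `eta` (lognormal mean correction) so the realized
  overall event rate is centred at the baseline.

What the generator does *not* emulate: reporting artefacts of real
surveillance data — retrospective capture bias, silent transfers,
under-reporting in early periods — or covariate measurement error and
spatial confounding. Passing recovery tests therefore show that the
estimator inverts its own generative model at realistic effect sizes and
counts, not that any real panel satisfies those assumptions.

## Numerical choices

- PSD checks tolerate eigenvalues down to `-1e-8`; rank thresholds use
  `1e-8` relative to the largest eigenvalue.
- Constraint checks in the log-prior tolerate `1e-8` per-element drift; the
  cached linear predictor is rebuilt from its components every 500
  iterations to kill float drift.
- Proposals that overflow the Poisson mean evaluate to non-finite and are
  auto-rejected (counted as rejections).
- Degenerate inputs: an all-zero count panel warns and runs (posterior
  driven by the priors); internal standardization refuses it; rank-0
  structures warn and return zero fields in simulation.
- Convergence is summarized with rank-normalized split R-hat and bulk ESS
  (arviz); any parameter with R-hat > 1.05 flags the fit as not converged.

## Problem sizes used by the shipped checks

The acceptance script fits 10 replicate panels (4x4 lattice, `Z = 8`) with
4 chains x 10,000 iterations (5,000 burn-in, thinning 4; 5,000 retained
draws per fit) — a desk-scale design whose Monte-Carlo error on the
averaged posterior-mean RR is well inside the +/-0.05 band. The
model-selection check uses 2 chains x 4,000 iterations per fit; DIC
differences of the magnitude involved (~5-10) are stable at that length.

## Known limitations

- Inference is MCMC, not a nested Laplace approximation; results agree in
  distribution but run times are minutes, not seconds, and very large
  panels (hundreds of regions) would need longer adaptation.
- The recentring convention for interaction constraints (above) is the
  standard approximation, not an exact constrained sampler.
- Type IV interactions, BYM2/PC-prior reparameterizations, non-Poisson
  likelihoods, CPO/PIT diagnostics and choropleth cartography are out of
  scope; surfaces are emitted as long-format tables (`plotting.trellis_heatmap`
  gives a quick look).
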