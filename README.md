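# stcar — Bayesian spatio-temporal Poisson disease mapping

`stcar` estimates area-level disease risk over time from count panels:
events `Y_it`, populations at risk `N_it` and covariates over `n` regions
and `Z` periods. It is built for surveillance-style questions — *which
regions are hotspots, when, and which programme factors move the risk?* —
the setting where outcomes such as HIV-care loss to follow-up are reported
as yearly counts per province rather than individual records.

The model is the Besag-York-Mollié (BYM) convolution extended in time with
Knorr-Held space-time interactions:

    Y_it ~ Poisson(E_it * lambda_it)
    log lambda_it = alpha + x_it' beta + u_i + v_i + gamma_t + psi_it

with `E_it` the expected counts (internal standardization by default),
`u` an intrinsic CAR (ICAR) spatial field on the region contiguity graph,
`v` iid spatial heterogeneity, `gamma` a first-order random-walk (RW1) time
trend, and `psi` a space-time interaction of Knorr-Held type I (iid),
II (independent RW1 per region) or III (independent ICAR per period).
Precisions get Gamma hyperpriors; intrinsic blocks are identified by
sum-to-zero constraints. Inference is Metropolis-within-Gibbs MCMC with
exact conjugate precision updates and collapsed/interweaved moves for the
aliased directions (see `docs/methods.md`). Fitted objects report
fixed-effect relative risks with credible intervals, cellwise relative-risk
surfaces `lambda_it`, exceedance probabilities `P(lambda_it > T | data)`,
and DIC/WAIC for model comparison.

A synthetic-data module generates panels with exactly this generative
structure at known parameter values — including a ready-made 10-province,
8-year scenario emulating an ART-programme loss-to-follow-up panel — so
every estimator is testable without restricted surveillance data.

## Worked example

Simulate the province scenario and fit the type II interaction model:

```python
from stcar import ModelSpec, SpatioTemporalPoissonModel, observed_rates
from stcar.simulate import zimbabwe_scenario, simulate_panel

data, truth = simulate_panel(zimbabwe_scenario(seed=1))
print(observed_rates(data, by="overall"))

model = SpatioTemporalPoissonModel(data, ModelSpec(interaction_type="II"))
result = model.fit(seed=20, n_iter=6000, n_burnin=2000, thin=4, n_chains=4)
print(result.summary())
```

Output (abridged):

```
 events     at_risk  rate  ci_lower  ci_upper
57781.0 284629.8664 0.203    0.2015    0.2045

Spatio-temporal Poisson disease-mapping model
============================================================
model:             interaction II
regions x periods: 10 x 8
retained draws:    4000 (4 chains)
converged:         yes

Fixed effects (relative risk, original covariate scale)
------------------------------------------------------------
  ...
  duration_art             RR  0.694 (0.566-0.842)

Model criteria
------------------------------------------------------------
  DIC      792.43   pD         78.22   Dbar     714.22
  WAIC     770.94   p_waic     40.81
```

The overall observed event rate of this realization is 20.3% (exact
binomial CI), close to the scenario's 22.7% baseline. The fitted relative
risk for mean years on ART is 0.694 (95% CrI 0.57–0.84) per year — the
posterior recovering the scenario's true protective effect of 0.651, i.e.
each extra year on treatment reduces the loss-to-follow-up risk by about a
third. DIC/WAIC are the comparison criteria; refitting with
`interaction_type` "I"/"III" and passing the results to `compare_models`
ranks the candidates on the same panel.

The risk surface and hotspot probabilities come in long format, ready for
mapping:

```python
result.rr_surface().head(3)
#   region  time  rr_mean  rr_lower  rr_upper  exceedance_prob
# Bulawayo     0    0.426     0.388     0.465              0.0
# Bulawayo     1    0.796     0.731     0.865              0.0
# Bulawayo     2    0.566     0.510     0.624              0.0
```

`exceedance_prob` is the posterior probability that a cell's relative risk
exceeds the threshold `T = 1` (configurable via `ModelSpec(threshold=...)`).

## Command line

The same pipeline is scriptable:

```bash
stcar simulate --zimbabwe --seed 7 --out runs/sim
stcar fit --panel runs/sim/panel.csv --adjacency runs/sim/adjacency.txt \
          --interaction II --seed 7 --out runs/fit2
stcar fit --panel runs/sim/panel.csv --adjacency runs/sim/adjacency.txt \
          --interaction I  --seed 7 --out runs/fit1
stcar compare runs/fit1 runs/fit2
```

Exit codes: 0 success, 2 validation error, 3 runtime failure. Every output
directory carries a provenance JSON (config, seeds, data hash) sufficient
to reproduce the run; `compare` refuses fits whose data hashes differ.

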