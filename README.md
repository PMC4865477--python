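# interocc

Hierarchical multi-species occupancy/abundance models with Bayesian variable
selection, for camera-trap detection histories.

Camera-trap surveys record, for each species, a binary site × occasion
detection history. Disentangling *how many animals use a site* from *how
detectable they are* — and how either quantity depends on the presence or
abundance of other species — requires a model that treats both as latent.
`interocc` is built for ecologists asking exactly that kind of question about
interacting assemblages (e.g., apex predators, mesopredators, and their prey)
sampled by camera arrays.

## The model

* **Royle–Nichols abundance submodel** per species: N_i ~ Poisson(λ_i) latent
  site abundance, detection probability induced by abundance,
  p_ij = 1 − (1 − r_ij)^{N_i}.
* **Occupancy submodel** where abundance is not meaningful at the camera
  scale: z_i ~ Bernoulli(ψ_i), y_ij ~ Bernoulli(p_ij z_i).
* **Species-interaction covariates**: the realized latent state of one
  species enters another's predictors, e.g. logit(ψ_A) = β_0 + β_1 z_B or
  log(λ_A) = β_0 + β_1 N_B, over a user-declared directed acyclic graph, on
  both state and detection parameters.
* **Gibbs variable selection**: every candidate covariate and interaction
  term carries an indicator w_k ~ Bernoulli(0.5); excluded coefficients are
  sampled from pilot-run pseudo-priors, and included ones share a
  per-predictor shrinkage variance Σ_k = V_θ/Σw with 1/V_θ ~ Γ(3.2890,
  7.8014).
* **Array random intercepts** on every predictor absorb spatial blocking, and
  per-array mean abundance/occurrence indices (N̄, z̄) are derived each
  iteration and correlated between species with a Bayesian bivariate model.

Everything is fitted by a Metropolis-within-Gibbs sampler with exact
enumerated updates for the discrete latents. See `docs/methods.md` for the
full statistical account.

Because no field dataset ships with the package, a first-class synthetic
generator (`interocc.simulate`) reproduces the assumed survey structure —
8 arrays × 31–36 cameras (281 sites), 3 occasions, array-clustered
covariates, and a six-species interaction DAG — with known ground truth for
every recovery test.

## Worked example

```python
import numpy as np
from interocc import (canid_scenario, simulate, McmcConfig,
                      run_pilot, run_selection, conditional_effect,
                      inclusion_probability)

cfg = canid_scenario(seed=3)          # six species, interaction DAG, 281 sites
truth = simulate(cfg)                 # detection histories + known truth
pilot_draws, pseudo = run_pilot(
    truth.data, truth.covariates, cfg.spec,
    McmcConfig(n_burnin=800, n_iter=800, n_chains=2, seed=1))
draws = run_selection(
    truth.data, truth.covariates, cfg.spec,
    McmcConfig(n_burnin=3000, n_iter=3000, n_chains=2, seed=2), pseudo)

cid = "red_fox.detection.int:coyote"  # true generating value: -0.9
print(round(inclusion_probability(draws, cid), 2))
e = conditional_effect(draws, cid)
print(round(e.cond_mean, 2), [round(v, 2) for v in e.cri85], e.directional_85)
```

prints (seed 3, this schedule):

```
1.0
-1.46 [-2.08, -0.92] True
```

i.e. the sampler assigns posterior probability 1.0 to the coyote→red-fox
detection interaction belonging in the model, and conditional on inclusion
estimates it at −1.46 with an 85% credible interval of (−2.08, −0.92) that
excludes zero — recovering the negative generating effect of −0.9: where
coyotes are abundant, red foxes are detected less.

The same workflow is scripted end to end in `analysis/01_simulate.py` …
`analysis/05_array_correlations.py` (outputs under `results/`), and a
YAML-driven CLI (`interocc simulate|fit|summarize|diagnose`) wraps it for
shell use.

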