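# Methods

## The model

`interocc` fits a hierarchical multi-species model for camera-trap detection
histories collected at sites grouped into spatial arrays.

**Royle–Nichols (RN) submodel.** For most species, site-level heterogeneity in
detection is attributed to latent relative abundance: N_i ~ Poisson(λ_i), and a
species-level detection on occasion j is Bernoulli with

    p_ij = 1 − (1 − r_ij)^{N_i},

where r is the per-individual detection probability. Without population
closure at a camera's trigger zone, λ is read as the expected number of
individuals using the site, not a closed local population.

**Occupancy submodel.** For species whose local density is dominated by group
structure (the wolf in the default scenario), latent occurrence replaces
abundance: z_i ~ Bernoulli(ψ_i), y_ij ~ Bernoulli(p_ij · z_i).

**Linear predictors.** Every state parameter (log λ, logit ψ) and detection
parameter (logit r, logit p) is a linear predictor with an intercept, site
covariates, an array-specific random intercept, and — for species with inbound
interaction edges — the *realized latent state* of other species:

    logit(ψ_A,i) = β_0 + Σ_k w_k β_k X_ki + α_{a(i)} + β_e z_B,i
    log(λ_A,i)  = β_0 + Σ_k w_k β_k X_ki + α_{a(i)} + β_e N_B,i

Latent interaction covariates enter raw (N uncentered, z ∈ {0,1}); they are
deliberately not standardized, so β_e is the per-individual (or
presence/absence) change on the link scale. The interaction graph must be a
DAG; species are processed in topological order so every source latent is
realized before its targets, both in simulation and in every MCMC sweep.

**Covariates.** Continuous covariates are standardized to mean 0, sd 0.5, which
puts them on a footing comparable with binary dummy variables; binary trail
attributes are left as 0/1.

## Variable selection (GVS)

Each selectable coefficient (all site covariates and all interaction terms;
not intercepts or random effects) carries an indicator w_k ~ Bernoulli(0.5).
While w_k = 1 the coefficient has the slab prior N(0, Σ_k); while w_k = 0 it is
resampled from a pseudo-prior — a normal matched to the coefficient's pilot
posterior mean and sd — so that indicator flips propose plausible values and
mix well. The slab variance is shared across each linear predictor θ:

    Σ_k = V_θ / Σ_k w_θk,   1/V_θ ~ Gamma(3.2890, 7.8014),

so the effective prior shrinks as more terms enter a predictor. The V_θ update
is the conjugate inverse-gamma full conditional (shape a + m/2, rate
b + (m/2)·Σβ²; prior draw when nothing is included), verified in the tests
against direct quadrature of likelihood × prior.

The indicator full conditional compares likelihood × slab × (slab densities of
the *other* included coefficients at variance V/m_on) against likelihood
without the term × pseudo-prior × (other coefficients at V/m_off); the m-shift
terms matter because flipping one indicator changes every included
coefficient's prior variance.

**Pilot stage.** The pseudo-priors come from a pilot fit of the full model
(all w ≡ 1) under flat Uniform(−10, 10) coefficient priors. Intercepts keep
the flat prior in both stages.

## Sampler

Metropolis-within-Gibbs, one sweep =

1. latent states in topological order — N_i resampled exactly from its
   enumerated full conditional on {0..N_max} (Gumbel-max trick over the
   candidate grid, jointly over sites, including the likelihood of all
   downstream predictors that read N_i); z_i from its Bernoulli full
   conditional, fixed at 1 wherever the species was detected;
2. per predictor: intercept (random-walk Metropolis), each coefficient
   (Metropolis while included, pseudo-prior draw while excluded), each
   indicator (Gibbs), the shared variance (conjugate), the array random
   intercepts (per-array Metropolis, vectorized) and their sd (log-scale
   Metropolis under a half-normal(2) prior).

N_max is max(20, the smallest bound leaving Poisson tail mass < 1e-6 at 1.15×
the current largest site λ), recomputed every 25 sweeps or sooner if λ grows
past the cached margin, and capped at 400. Proposal scales adapt every 50
iterations during burn-in toward ~40% acceptance and are frozen afterwards, so
retained draws come from a fixed, detailed-balance-preserving kernel.

Initialization: N = 2 at detected sites (observed maximum + 1 for binary
histories) else Poisson(1); z = 1 at detected sites else Bernoulli(0.5);
coefficients 0; all w = 1; V at its prior mean. One master seed spawns
independent per-chain streams; all results are bit-reproducible from
(config, seed).

The likelihood kernels the sampler uses are algebraically specialized
(cached log-factorials, detection-site restriction of the expensive
`log(−expm1(·))` term); tests assert their exact agreement with the plain
reference kernels in `interocc.likelihoods`, whose marginal (latent-summed)
forms also serve as enumeration oracles.

## Inference statistics

Two statistics per candidate term: the posterior inclusion probability
(mean of w_k) and the conditional effect summary (posterior of β_k over draws
with w_k = 1; chains pooled by concatenation before conditioning). Credible
intervals are equal-tailed quantile intervals by default (HPD available as an
option). Because shrinkage and collinearity can depress inclusion
probabilities of genuinely influential terms, directional confidence is
flagged when the 85% CRI excludes zero, with the 95% interval reported
alongside. Convergence is monitored with the classic between/within-chain
potential scale reduction factor (threshold 1.1); constant chains return 1.0
by convention.

## Derived indices and correlations

At every retained iteration the mean latent abundance (N̄) or occurrence (z̄)
over the sites of each array is recorded. Post hoc associations between two
species are the posterior of the correlation ρ under a bivariate normal
location-scale model fitted by Metropolis-within-Gibbs with flat priors on
locations, log-scale-flat priors on scales, and Uniform(−1, 1) on ρ; a
heavy-tailed bivariate-t option (df − 1 ~ Exponential(1/29)) is available.
The default correlates posterior-mean indices per array (n = number of
arrays); full uncertainty propagation over posterior draws is provided as an
option. With 8 arrays the ρ posterior is wide by design; sign and bulk
direction are the interpretable outputs.

## Synthetic-data generator

The generator emulates the survey the model assumes: 8 arrays of 31–36
cameras (281 sites total by default), 3 occasions, a ~5% per-cell camera
failure rate (failed cells are missing, never zero), continuous land-cover
covariates clustered by array (array-level mean plus site-level noise of equal
sd, then standardized), one array-scale covariate constant within arrays,
i.i.d. Bernoulli(0.5) binary trail covariates, array random intercepts
(sd 0.25 by default) on every predictor, and generation in topological order
of the interaction DAG.

The default six-species scenario uses round synthetic effect sizes in
[−1, 1] — deliberately not any field study's estimates — with intercepts tuned
once so the naive detection frequencies reproduce a realistic ordering
(ubiquitous deer, common coyote, ~30% lagomorph/wolf, rare foxes). Strong
site-level effects (|β| ≥ 0.9: the deer cropland effect on abundance and the
negative coyote→red fox detection interaction) are the targets of the recovery
tests.

What the generator does not emulate: spatial autocorrelation beyond the
one-level array clustering, animal movement or home-range overlap between
cameras, temporal (multi-season) dynamics, and misidentification. Passing
recovery tests therefore demonstrates correctness of the estimator under the
model's own assumptions, not robustness to their violation in field data.

## Known limitations and numerical choices

* **Array-scale covariates are confounded with array random intercepts.** A
  covariate taking a single value per array (8 distinct values) competes
  directly with 8 free random intercepts; its inclusion probability hovers
  near the prior regardless of the true effect. The generator keeps such a
  covariate (wolf state, β = −1) precisely because the ambiguity is a real
  feature of blocked designs, but recovery tests assess only site-level
  effects.
* **Detection-level interactions on rare species are sign-identified but not
  reliably interval-identified at this design scale.** The coyote→red fox
  detection effect (true −0.9) illustrates the limit: the fox is detected at
  ~15% of 281 sites, its own abundance is latent, and the detection edge is
  collinear with the state-level edge from the same source species, so
  selection-stage model-mixing spreads the conditional posterior. Across
  validation replicates the conditional mean has the correct sign essentially
  always, but the 85% CRI excludes zero in only roughly half of single
  datasets; even the full-model flat-prior posterior puts the effect only
  ~2.5 posterior sd from zero. Pooling across replicates, larger surveys, or
  more occasions would be needed for reliable interval-level detection.
* An all-zero detection history leaves λ and r only jointly identified; the
  posterior concentrates on negligible *implied* detection rather than on any
  single parameter.
* Occasions are abstract columns (default 3 per deployment, configurable);
  detection parameters are site-level, so occasions are exchangeable given
  the state.
* With a single array the random intercept is confounded with the global
  intercept; the sampler still runs, and the draws remain valid for the sum.
* Problem sizes in tests and in `scripts/acceptance.py` use reduced MCMC
  schedules (hundreds to a few thousand burn-in/retained iterations, 1–2
  chains) chosen to give stable Monte-Carlo behaviour at desk scale; the
  package defaults mirror much longer schedules (50k/150k thinned by 10 over
  4 chains for the pilot; 300k/200k for selection) appropriate for real
  analyses.
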