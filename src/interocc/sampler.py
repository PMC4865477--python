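"""Metropolis-within-Gibbs sampler with Gibbs variable selection (GVS).

The joint model factorizes over species given their latent states, so one
MCMC sweep visits, in topological order of the interaction DAG, the latent
abundances N (discrete full conditional, enumerated up to an adaptive
truncation bound) and occurrences z (Bernoulli full conditional), then for
every linear predictor its intercept, coefficients, inclusion indicators,
shared prior variance, and array random intercepts.

Variable selection follows the pseudo-prior recipe: each selectable
coefficient carries an indicator w_k ~ Bernoulli(0.5); while w_k = 1 the
coefficient has slab prior Normal(0, Sigma_k) with the shared-variance
structure Sigma_k = V_theta / sum_k(w_k) and 1/V_theta ~ Gamma(3.2890,
7.8014), and while w_k = 0 it is resampled from a pseudo-prior matched to a
pilot run's posterior (mean and sd), so indicator flips propose plausible
values.  The pilot run fits the full model (all w = 1) under flat
Uniform(-10, 10) coefficient priors.

Random-walk proposal scales adapt toward ~40% acceptance during burn-in and
are frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln

from .data import (ABUNDANCE_RN, DETECTION, LATENT_N, STATE, CovariateTable,
                   DetectionData, ModelSpec, topological_order)
from .inference import PosteriorDraws, gelman_rubin
from .likelihoods import (LatentState, LinearPredictorSpec,
                          poisson_truncation_bound)

#: Prior on the per-predictor shared variance: 1/V ~ Gamma(shape, rate).
IG_SHAPE = 3.2890
IG_RATE = 7.8014
#: Flat prior bound for intercepts always, and for coefficients in pilot mode.
BETA_BOUND = 10.0
#: Half-normal prior scale for random-intercept standard deviations.
RANDOM_SD_PRIOR_SCALE = 2.0
#: Hard cap on the latent-abundance enumeration grid.
N_ENUM_CAP = 400


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class McmcConfig:
    """MCMC schedule. ``n_iter`` counts post-burn-in iterations per chain;
    ``n_iter // thin`` draws are retained."""

    n_burnin: int
    n_iter: int
    n_chains: int = 4
    thin: int = 1
    seed: int = 0
    adapt_iters: int | None = None  # defaults to the burn-in length

    def __post_init__(self):
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise ValueError("n_iter must be positive and n_burnin non-negative")
        if self.thin < 1 or self.n_iter % self.thin:
            raise ValueError("thin must be >= 1 and divide n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PseudoPrior:
    """Normal pseudo-prior per selectable coefficient (pilot mean and sd)."""

    loc: dict
    scale: dict

    def logpdf(self, coef: str, x: float) -> float:
        if coef not in self.loc:
            raise KeyError(f"no pseudo-prior for {coef!r}; run the pilot first")
        mu, sd = self.loc[coef], self.scale[coef]
        return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2

    def draw(self, coef: str, rng) -> float:
        if coef not in self.loc:
            raise KeyError(f"no pseudo-prior for {coef!r}; run the pilot first")
        return float(rng.normal(self.loc[coef], self.scale[coef]))


@dataclass
class ParameterState:
    """A snapshot of one MCMC state for inspection and testing."""

    predictors: dict            # (species, param) -> LinearPredictorSpec
    shared_variance: dict       # (species, param) -> V_theta
    random_effect_sd: dict      # (species, param) -> sd
    latents: LatentState
    n_max: dict = field(default_factory=dict)


class _Block:
    """Runtime state of one linear predictor (one species x state/detection)."""

    __slots__ = ("species", "param", "kind", "link", "terms", "coef_ids",
                 "beta", "w", "intercept", "alpha", "sigma", "V", "eta",
                 "cur_ll", "scale", "scale_int", "scale_alpha", "scale_lsig",
                 "acc", "att", "acc_int", "att_int")

    def __init__(self, species, param, kind, link, terms, coef_ids, n_arrays):
        self.species, self.param, self.kind, self.link = species, param, kind, link
        self.terms = terms          # list of ("cov", x_array) or ("edge", source, quantity)
        self.coef_ids = coef_ids
        K = len(terms)
        self.beta = np.zeros(K)
        self.w = np.ones(K, dtype=np.int64)
        self.intercept = 0.0
        self.alpha = np.zeros(n_arrays)
        self.sigma = 0.5
        self.V = IG_RATE / (IG_SHAPE - 1.0)  # prior mean of V
        self.eta = None
        self.cur_ll = None
        self.scale = np.full(K, 0.3)
        self.scale_int = 0.3
        self.scale_alpha = 0.3
        self.scale_lsig = 0.5
        self.acc = np.zeros(K)
        self.att = np.zeros(K)
        self.acc_int = 0.0
        self.att_int = 0.0


class GibbsSampler:
    """One-chain sampler; :func:`run_pilot` / :func:`run_selection` drive it.

    Parameters
    ----------
    pilot
        Pilot mode: all indicators fixed at 1, flat Uniform(-10, 10)
        coefficient priors, no shared-variance updates.
    pseudo
        Pseudo-priors from a pilot run; required when selection is active.
    """

    def __init__(self, data: DetectionData, covs: CovariateTable, spec: ModelSpec,
                 rng=None, pilot: bool = False, pseudo: PseudoPrior | None = None):
        self.spec = spec
        self.design = data.design
        self.covs = covs
        self.rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.pilot = pilot
        self.selection = spec.selection_enabled and not pilot
        if self.selection and pseudo is None:
            raise ValueError("selection requires pseudo-priors from a pilot run")
        self.pseudo = pseudo
        self.order = topological_order(spec)
        self.J = data.effort().astype(float)
        self.d = {sp: data.detections(sp).astype(float) for sp in spec.species}
        self._det_sites = {sp: self.d[sp] > 0 for sp in spec.species}
        n = self.design.n_sites

        # latent initialization: presence forced wherever the species was seen
        self.N, self.z = {}, {}
        for sp in spec.species:
            det = self.d[sp] > 0
            if spec.submodel_of_species[sp] == ABUNDANCE_RN:
                self.N[sp] = np.where(det, 2, self.rng.poisson(1.0, n)).astype(np.int64)
            else:
                self.z[sp] = np.where(det, 1, self.rng.integers(0, 2, n)).astype(np.int64)
        self._lgamN = {sp: gammaln(self.N[sp] + 1.0) for sp in self.N}

        self.blocks = {}
        for sp in spec.species:
            rn = spec.submodel_of_species[sp] == ABUNDANCE_RN
            for param in (STATE, DETECTION):
                kind = (("rn_" if rn else "occ_") +
                        ("state" if param == STATE else "det"))
                link = "log" if kind == "rn_state" else "logit"
                terms, ids = [], []
                for name in spec.covariates_of(sp, param):
                    terms.append(("cov", covs.column(name)))
                    ids.append(f"{sp}.{param}.{name}")
                for e in spec.interactions_into(sp, param):
                    terms.append(("edge", e.source, e.source_quantity))
                    ids.append(f"{sp}.{param}.{e.label()}")
                self.blocks[(sp, param)] = _Block(sp, param, kind, link, terms,
                                                 ids, self.design.n_arrays)

        # downstream map: species -> [(block, term index)] reading its latent
        self.downstream = {sp: [] for sp in spec.species}
        for b in self.blocks.values():
            for k, t in enumerate(b.terms):
                if t[0] == "edge":
                    self.downstream[t[1]].append((b, k))

        self.n_max = {}
        self._nmax_ref = {}   # species -> lambda_max the cached bound covers
        self._sweeps = 0
        self._asite = self.design.array_of_site
        self._acount = np.bincount(self._asite, minlength=self.design.n_arrays)
        for b in self.blocks.values():
            b.eta = self._compute_eta(b)
            self._refresh(b)

    # -- predictor plumbing ------------------------------------------------

    def _x(self, block: _Block, k: int) -> np.ndarray:
        t = block.terms[k]
        if t[0] == "cov":
            return t[1]
        store = self.N if t[2] == LATENT_N else self.z
        return store[t[1]].astype(float)

    def _compute_eta(self, b: _Block) -> np.ndarray:
        eta = np.full(self.design.n_sites, b.intercept)
        if self.spec.random_intercepts:
            eta = eta + b.alpha[self._asite]
        for k in range(len(b.terms)):
            if b.w[k]:
                eta = eta + b.beta[k] * self._x(b, k)
        return eta

    def _loglik_sites(self, b: _Block, eta) -> np.ndarray:
        # fast equivalents of the likelihoods-module kernels: gammaln(N+1) is
        # cached per species, and the expensive log(-expm1(.)) / logit terms
        # are evaluated only at detected (resp. occupied) sites.  Equality
        # with the reference kernels is covered by tests.
        sp = b.species
        if b.kind == "rn_state":
            return self.N[sp] * eta - np.exp(eta) - self._lgamN[sp]
        if b.kind == "rn_det":
            N, d, J = self.N[sp], self.d[sp], self.J
            det = self._det_sites[sp]
            log_miss = N * -np.logaddexp(0.0, eta)
            ll = (J - d) * log_miss
            with np.errstate(divide="ignore"):
                ll[..., det] += d[det] * np.log(-np.expm1(log_miss[..., det]))
            return ll
        if b.kind == "occ_state":
            return self.z[sp] * eta - np.logaddexp(0.0, eta)
        d, J = self.d[sp], self.J
        occ = self.z[sp] == 1
        out = np.zeros(eta.shape)
        e = eta[..., occ]
        out[..., occ] = (d[occ] * -np.logaddexp(0.0, -e)
                         + (J[occ] - d[occ]) * -np.logaddexp(0.0, e))
        return out

    def _loglik_sum(self, b: _Block, eta) -> float:
        return float(self._loglik_sites(b, eta).sum())

    def _refresh(self, b: _Block) -> None:
        b.cur_ll = self._loglik_sum(b, b.eta)

    # -- latent-state updates ---------------------------------------------

    def update_latent_N(self, species: str) -> None:
        """Resample latent abundance at every site from its full conditional.

        The conditional at site i is proportional to Poisson(N; lambda_i)
        times the species' own detection likelihood times the likelihood of
        every downstream predictor reading N_i; it is enumerated on
        0..N_max and sampled exactly (Gumbel-max).  Sites with a detection
        get zero mass at N = 0.
        """
        bs = self.blocks[(species, STATE)]
        bd = self.blocks[(species, DETECTION)]
        lam_max = float(np.exp(min(bs.eta.max(), 20.0)))
        # truncation bound recomputed per block of sweeps, or when lambda grows
        # past the margin the cached bound was computed for
        if (species not in self.n_max or self._sweeps % 25 == 0
                or lam_max > self._nmax_ref[species]):
            ref = 1.15 * lam_max
            self.n_max[species] = min(poisson_truncation_bound(ref), N_ENUM_CAP)
            self._nmax_ref[species] = ref
        n_max = self.n_max[species]
        cand = np.arange(n_max + 1, dtype=float)
        d, J = self.d[species], self.J
        det = self._det_sites[species]
        logw = cand[:, None] * bs.eta[None, :] - gammaln(cand + 1.0)[:, None]
        # own detection term: (J-d) N log(1-r) everywhere; the d log p part
        # only exists at sites with a detection
        log1mr = -np.logaddexp(0.0, bd.eta)
        log_miss = cand[:, None] * log1mr[None, :]
        logw += (J - d) * log_miss
        with np.errstate(divide="ignore"):
            logw[1:, det] += d[det] * np.log(-np.expm1(log_miss[1:, det]))
        logw[0, det] = -np.inf
        old = self.N[species]
        for tb, k in self.downstream[species]:
            c = tb.w[k] * tb.beta[k]
            if c != 0.0:
                eta_c = tb.eta[None, :] + c * (cand[:, None] - old[None, :])
                logw += self._loglik_sites(tb, eta_c)
        g = self.rng.gumbel(size=logw.shape)
        new = np.argmax(logw + g, axis=0).astype(np.int64)
        delta = (new - old).astype(float)
        self.N[species] = new
        self._lgamN[species] = gammaln(new + 1.0)
        for tb, k in self.downstream[species]:
            c = tb.w[k] * tb.beta[k]
            if c != 0.0:
                tb.eta += c * delta
                self._refresh(tb)
        self._refresh(bs)
        self._refresh(bd)

    def update_latent_z(self, species: str) -> None:
        """Resample latent occurrence from its Bernoulli full conditional.

        Detected sites stay occupied; elsewhere the log-odds combine the
        state predictor, the probability of the all-zero history, and any
        downstream likelihood terms reading z_i.
        """
        bs = self.blocks[(species, STATE)]
        bd = self.blocks[(species, DETECTION)]
        d = self.d[species]
        log_p = -np.logaddexp(0.0, -bd.eta)
        log_q = -np.logaddexp(0.0, bd.eta)
        logodds = bs.eta + d * log_p + (self.J - d) * log_q
        old = self.z[species]
        for tb, k in self.downstream[species]:
            c = tb.w[k] * tb.beta[k]
            if c != 0.0:
                ll1 = self._loglik_sites(tb, tb.eta + c * (1.0 - old))
                ll0 = self._loglik_sites(tb, tb.eta + c * (0.0 - old))
                logodds += ll1 - ll0
        p1 = expit(logodds)
        new = np.where(d > 0, 1, (self.rng.random(p1.size) < p1)).astype(np.int64)
        delta = (new - old).astype(float)
        self.z[species] = new
        for tb, k in self.downstream[species]:
            c = tb.w[k] * tb.beta[k]
            if c != 0.0:
                tb.eta += c * delta
                self._refresh(tb)
        self._refresh(bs)
        self._refresh(bd)

    def update_latents(self) -> None:
        for sp in self.order:
            if self.spec.submodel_of_species[sp] == ABUNDANCE_RN:
                self.update_latent_N(sp)
            else:
                self.update_latent_z(sp)

    # -- coefficient updates ----------------------------------------------

    def _slab_logpdf_sum(self, m: int, ssq: float, V: float) -> float:
        """Sum of log N(beta_j; 0, V/m) over m included coefficients with
        total sum of squares ssq."""
        if m == 0:
            return 0.0
        v = V / m
        return -0.5 * m * np.log(2 * np.pi * v) - ssq / (2.0 * v)

    def update_beta(self, key, k: int) -> None:
        """Random-walk Metropolis step for one coefficient (or a pseudo-prior
        draw while its indicator is off)."""
        b = self.blocks[key]
        if self.selection and b.w[k] == 0:
            b.beta[k] = self.pseudo.draw(b.coef_ids[k], self.rng)
            return
        old = b.beta[k]
        new = old + self.rng.normal(0.0, b.scale[k])
        b.att[k] += 1
        if self.pilot or not self.selection:
            if abs(new) > BETA_BOUND:
                return
            dprior = 0.0
        else:
            m = int(b.w.sum())
            dprior = -0.5 * m / b.V * (new * new - old * old)
        eta_new = b.eta + (new - old) * self._x(b, k)
        ll_new = self._loglik_sum(b, eta_new)
        if np.log(self.rng.random()) < ll_new - b.cur_ll + dprior:
            b.beta[k] = new
            b.eta = eta_new
            b.cur_ll = ll_new
            b.acc[k] += 1

    def update_intercept(self, key) -> None:
        b = self.blocks[key]
        old = b.intercept
        new = old + self.rng.normal(0.0, b.scale_int)
        b.att_int += 1
        if abs(new) > BETA_BOUND:
            return
        eta_new = b.eta + (new - old)
        ll_new = self._loglik_sum(b, eta_new)
        if np.log(self.rng.random()) < ll_new - b.cur_ll:
            b.intercept = new
            b.eta = eta_new
            b.cur_ll = ll_new
            b.acc_int += 1

    def update_inclusion(self, key, k: int) -> None:
        """Gibbs step for one indicator w_k.

        The odds compare the likelihood and slab prior with the term active
        (all included coefficients then have prior variance V/m_on) against
        the likelihood without it and the pseudo-prior density at the current
        beta (coefficients then sit at variance V/m_off).  The Bernoulli(0.5)
        prior on w cancels.
        """
        if not self.selection:
            raise RuntimeError("inclusion updates require selection mode")
        b = self.blocks[key]
        beta_k = b.beta[k]
        x = self._x(b, k)
        incl_ssq = float(((b.w * b.beta) ** 2).sum())
        if b.w[k] == 1:
            ll_on, eta_off = b.cur_ll, b.eta - beta_k * x
            ll_off = self._loglik_sum(b, eta_off)
            m_on = int(b.w.sum())
            ssq_other = incl_ssq - beta_k * beta_k
        else:
            ll_off, eta_on = b.cur_ll, b.eta + beta_k * x
            ll_on = self._loglik_sum(b, eta_on)
            m_on = int(b.w.sum()) + 1
            ssq_other = incl_ssq
        m_off = m_on - 1
        log_on = ll_on + self._slab_logpdf_sum(m_on, ssq_other + beta_k * beta_k, b.V)
        log_off = (ll_off + self.pseudo.logpdf(b.coef_ids[k], beta_k)
                   + self._slab_logpdf_sum(m_off, ssq_other, b.V))
        p_on = expit(log_on - log_off)
        w_new = int(self.rng.random() < p_on)
        if w_new != b.w[k]:
            b.w[k] = w_new
            if w_new == 1:
                b.eta, b.cur_ll = eta_on, ll_on
            else:
                b.eta, b.cur_ll = eta_off, ll_off

    def update_shared_variance(self, key) -> None:
        """Conjugate inverse-gamma update of the predictor's shared variance.

        Included coefficients are N(0, V/m) given V, so the precision 1/V has
        Gamma full conditional with shape ``a + m/2`` and rate
        ``b + (m/2) * sum(beta^2)``; with nothing included the draw comes
        from the prior.
        """
        b = self.blocks[key]
        m = int(b.w.sum())
        ssq = float(((b.w * b.beta) ** 2).sum())
        tau = self.rng.gamma(IG_SHAPE + 0.5 * m, 1.0 / (IG_RATE + 0.5 * m * ssq))
        b.V = 1.0 / tau

    def update_random_intercepts(self, key) -> None:
        """Per-array Metropolis updates of the random intercepts, then a
        log-scale Metropolis update of their standard deviation under a
        half-normal prior."""
        b = self.blocks[key]
        A = self.design.n_arrays
        ll_sites = self._loglik_sites(b, b.eta)
        delta = self.rng.normal(0.0, b.scale_alpha, size=A)
        ll_new_sites = self._loglik_sites(b, b.eta + delta[self._asite])
        dll = np.bincount(self._asite, weights=ll_new_sites - ll_sites, minlength=A)
        s2 = b.sigma * b.sigma
        dprior = -0.5 * ((b.alpha + delta) ** 2 - b.alpha ** 2) / s2
        accept = np.log(self.rng.random(A)) < dll + dprior
        step = delta * accept
        b.alpha = b.alpha + step
        b.eta = b.eta + step[self._asite]
        b.cur_ll += float(dll[accept].sum())

        # sd update on the log scale (Jacobian +log sigma)
        ssq_alpha = float((b.alpha ** 2).sum())

        def logpost_sigma(s):
            return (-A * np.log(s) - ssq_alpha / (2 * s * s)
                    - s * s / (2 * RANDOM_SD_PRIOR_SCALE ** 2) + np.log(s))

        new_sigma = b.sigma * np.exp(self.rng.normal(0.0, b.scale_lsig))
        if np.log(self.rng.random()) < logpost_sigma(new_sigma) - logpost_sigma(b.sigma):
            b.sigma = new_sigma

    # -- sweeps and recording ---------------------------------------------

    def sweep(self) -> None:
        self._sweeps += 1
        self.update_latents()
        for key, b in self.blocks.items():
            self.update_intercept(key)
            for k in range(len(b.terms)):
                self.update_beta(key, k)
            if self.selection:
                for k in range(len(b.terms)):
                    self.update_inclusion(key, k)
                self.update_shared_variance(key)
            if self.spec.random_intercepts:
                self.update_random_intercepts(key)

    def _adapt(self, batch: int) -> None:
        for b in self.blocks.values():
            with np.errstate(invalid="ignore"):
                rate = np.where(b.att > 0, b.acc / np.maximum(b.att, 1), 0.4)
            b.scale = np.clip(b.scale * np.exp(rate - 0.4), 1e-3, 10.0)
            b.acc[:] = 0.0
            b.att[:] = 0.0
            if b.att_int > 0:
                r = b.acc_int / b.att_int
                b.scale_int = float(np.clip(b.scale_int * np.exp(r - 0.4), 1e-3, 10.0))
            b.acc_int = b.att_int = 0.0

    def acceptance_rates(self) -> dict:
        """Post-adaptation acceptance rate per coefficient id."""
        out = {}
        for b in self.blocks.values():
            for k, cid in enumerate(b.coef_ids):
                if b.att[k] > 0:
                    out[cid] = b.acc[k] / b.att[k]
        return out

    def record_names(self) -> list:
        names = []
        for (sp, param), b in self.blocks.items():
            names.append(f"{sp}.{param}.(Intercept)")
            names.extend(b.coef_ids)
            if self.selection:
                names.extend(f"w:{c}" for c in b.coef_ids)
                names.append(f"V:{sp}.{param}")
            if self.spec.random_intercepts:
                names.append(f"sd_array:{sp}.{param}")
                names.extend(f"alpha:{sp}.{param}[{a}]"
                             for a in self.design.array_names)
        for sp in self.order:
            tag = "Nbar" if self.spec.submodel_of_species[sp] == ABUNDANCE_RN else "zbar"
            names.extend(f"{tag}:{sp}[{a}]" for a in self.design.array_names)
        return names

    def _record(self, out: dict, t: int) -> None:
        for (sp, param), b in self.blocks.items():
            out[f"{sp}.{param}.(Intercept)"][t] = b.intercept
            for k, cid in enumerate(b.coef_ids):
                out[cid][t] = b.beta[k]
                if self.selection:
                    out[f"w:{cid}"][t] = b.w[k]
            if self.selection:
                out[f"V:{sp}.{param}"][t] = b.V
            if self.spec.random_intercepts:
                out[f"sd_array:{sp}.{param}"][t] = b.sigma
                for a, aname in enumerate(self.design.array_names):
                    out[f"alpha:{sp}.{param}[{aname}]"][t] = b.alpha[a]
        for sp in self.order:
            rn = self.spec.submodel_of_species[sp] == ABUNDANCE_RN
            lat = self.N[sp] if rn else self.z[sp]
            sums = np.bincount(self._asite, weights=lat,
                               minlength=self.design.n_arrays)
            means = sums / self._acount
            tag = "Nbar" if rn else "zbar"
            for a, aname in enumerate(self.design.array_names):
                out[f"{tag}:{sp}[{aname}]"][t] = means[a]

    def run(self, n_burnin: int, n_iter: int, thin: int = 1,
            adapt_iters: int | None = None) -> dict:
        """Run one chain; returns {name: retained draw vector}."""
        adapt_iters = n_burnin if adapt_iters is None else min(adapt_iters, n_burnin)
        n_keep = n_iter // thin
        out = {name: np.empty(n_keep) for name in self.record_names()}
        t = 0
        for it in range(n_burnin + n_iter):
            self.sweep()
            if it < adapt_iters and (it + 1) % 50 == 0:
                self._adapt(50)
            if it >= n_burnin and (it - n_burnin) % thin == thin - 1:
                self._record(out, t)
                t += 1
        return out

    # -- state export ------------------------------------------------------

    def snapshot(self) -> ParameterState:
        preds, Vs, sds = {}, {}, {}
        for (sp, param), b in self.blocks.items():
            coeffs, incl = {}, {}
            for k, cid in enumerate(b.coef_ids):
                term = cid.split(".", 2)[2]
                coeffs[term] = float(b.beta[k])
                incl[term] = int(b.w[k])
            preds[(sp, param)] = LinearPredictorSpec(
                intercept=float(b.intercept), coefficients=coeffs, inclusion=incl,
                link=b.link,
                random_intercept_by_array={a: float(v) for a, v in enumerate(b.alpha)})
            Vs[(sp, param)] = float(b.V)
            sds[(sp, param)] = float(b.sigma)
        latents = LatentState(N={k: v.copy() for k, v in self.N.items()},
                              z={k: v.copy() for k, v in self.z.items()})
        return ParameterState(predictors=preds, shared_variance=Vs,
                              random_effect_sd=sds, latents=latents,
                              n_max=dict(self.n_max))


# ---------------------------------------------------------------------------
# multi-chain drivers
# ---------------------------------------------------------------------------


def _run_chains(data, covs, spec, cfg: McmcConfig, pilot: bool,
                pseudo: PseudoPrior | None, stage: str) -> PosteriorDraws:
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    per_chain = []
    coef_ids = None
    for c in range(cfg.n_chains):
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(seeds[c]),
                         pilot=pilot, pseudo=pseudo)
        per_chain.append(s.run(cfg.n_burnin, cfg.n_iter, cfg.thin, cfg.adapt_iters))
        if coef_ids is None:
            coef_ids = [cid for b in s.blocks.values() for cid in b.coef_ids]
    draws = {name: np.stack([rec[name] for rec in per_chain])
             for name in per_chain[0]}
    manifest = {"stage": stage, "seed": cfg.seed, "n_chains": cfg.n_chains,
                "n_burnin": cfg.n_burnin, "n_iter": cfg.n_iter, "thin": cfg.thin,
                "selection": spec.selection_enabled and not pilot,
                "random_intercepts": spec.random_intercepts,
                "priors": {"inv_V_gamma_shape": IG_SHAPE, "inv_V_gamma_rate": IG_RATE,
                           "pilot_beta_bound": BETA_BOUND,
                           "random_sd_half_normal_scale": RANDOM_SD_PRIOR_SCALE}}
    pd_ = PosteriorDraws(draws=draws, coefficients=coef_ids, manifest=manifest)
    if cfg.n_chains >= 2:
        bad = [(n, gelman_rubin(pd_.get(n))) for n in pd_.names
               if np.isfinite(pd_.get(n)).all()]
        bad = [(n, r) for n, r in bad if r >= 1.1]
        if bad:
            worst = sorted(bad, key=lambda x: -x[1])[:10]
            warnings.warn(f"{len(bad)} parameters with R-hat >= 1.1, e.g. "
                          + ", ".join(f"{n}={r:.3f}" for n, r in worst),
                          ConvergenceWarning)
    return pd_


def run_pilot(data: DetectionData, covs: CovariateTable, spec: ModelSpec,
              cfg: McmcConfig):
    """Fit the full model (all terms included, flat coefficient priors) and
    derive normal pseudo-priors from each coefficient's posterior mean/sd.

    Returns ``(draws, pseudo_prior)``.  Non-convergence (any R-hat >= 1.1
    with >= 2 chains) emits a :class:`ConvergenceWarning`; draws are still
    returned.
    """
    pilot_spec = replace_selection(spec, False)
    pd_ = _run_chains(data, covs, pilot_spec, cfg, pilot=True, pseudo=None,
                      stage="pilot")
    loc, scale = {}, {}
    for cid in pd_.coefficients:
        x = pd_.pooled(cid)
        loc[cid] = float(x.mean())
        scale[cid] = float(max(x.std(ddof=1), 1e-3))
    return pd_, PseudoPrior(loc=loc, scale=scale)


def run_selection(data: DetectionData, covs: CovariateTable, spec: ModelSpec,
                  cfg: McmcConfig, pseudo: PseudoPrior) -> PosteriorDraws:
    """Full GVS fit: latents in topological order, coefficients, indicators,
    shared variances, random intercepts; array-level indices recorded per
    retained iteration."""
    if spec.selection_enabled and pseudo is None:
        raise ValueError("run_selection needs the pilot's pseudo-priors")
    return _run_chains(data, covs, spec, cfg, pilot=False, pseudo=pseudo,
                       stage="selection")


def replace_selection(spec: ModelSpec, enabled: bool) -> ModelSpec:
    return ModelSpec(species=list(spec.species),
                     submodel_of_species=dict(spec.submodel_of_species),
                     state_covariates={k: list(v) for k, v in spec.state_covariates.items()},
                     detection_covariates={k: list(v) for k, v in spec.detection_covariates.items()},
                     interactions=list(spec.interactions),
                     selection_enabled=enabled,
                     random_intercepts=spec.random_intercepts)
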