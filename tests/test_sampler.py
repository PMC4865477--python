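import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import interocc.likelihoods as L
from interocc.data import (ABUNDANCE_RN, DETECTION, LATENT_N, OCCUPANCY, STATE,
                           CovariateTable, DetectionData, Interaction, ModelSpec)
from interocc.sampler import (IG_RATE, IG_SHAPE, GibbsSampler, McmcConfig,
                              PseudoPrior, run_pilot, run_selection,
                              replace_selection)

from conftest import make_design, occupancy_dataset, rn_dataset


def set_intercept(s, key, value):
    b = s.blocks[key]
    b.intercept = value
    b.eta = s._compute_eta(b)
    s._refresh(b)


def all_zero_dataset(kind, n_sites, J=2, extra_covs=None, selection=False):
    design = make_design(n_sites, J)
    y = np.zeros((n_sites, J), np.int8)
    data = DetectionData(histories={"sp": y}, design=design)
    covs = CovariateTable(continuous=extra_covs or {}, binary={})
    spec = ModelSpec(species=["sp"], submodel_of_species={"sp": kind},
                     state_covariates={"sp": list(extra_covs or {})},
                     detection_covariates={"sp": []},
                     selection_enabled=selection, random_intercepts=False)
    return data, covs, spec


class TestConfig:
    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            McmcConfig(n_burnin=10, n_iter=0)

    def test_thin_must_divide(self):
        with pytest.raises(ValueError, match="thin"):
            McmcConfig(n_burnin=10, n_iter=10, thin=3)

    def test_selection_without_pseudo_rejected(self):
        data, covs, spec = all_zero_dataset(OCCUPANCY, 5, selection=True)
        with pytest.raises(ValueError, match="pseudo"):
            GibbsSampler(data, covs, spec)


class TestDeterminism:
    def test_identical_draws_for_identical_config(self):
        data, covs, spec, _ = occupancy_dataset(0.6, 0.4, 60, seed=3)
        cfg = McmcConfig(n_burnin=50, n_iter=100, n_chains=2, seed=9)
        a, _ = run_pilot(data, covs, spec, cfg)
        b, _ = run_pilot(data, covs, spec, cfg)
        for name in a.names:
            np.testing.assert_array_equal(a.get(name), b.get(name))


class TestLatentZ:
    def test_closed_form_posterior_probability(self):
        # psi=0.7, two misses at p=0.4: P(z=1|y) = .7*.36/(.7*.36+.3)
        data, covs, spec = all_zero_dataset(OCCUPANCY, 4000, J=2)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(1), pilot=True)
        set_intercept(s, ("sp", STATE), logit(0.7))
        set_intercept(s, ("sp", DETECTION), logit(0.4))
        draws = []
        for _ in range(5):
            s.update_latent_z("sp")
            draws.append(s.z["sp"].copy())
        frac = np.concatenate(draws).mean()
        want = 0.7 * 0.36 / (0.7 * 0.36 + 0.3)
        assert frac == pytest.approx(want, abs=4 * np.sqrt(want * (1 - want) / 20000))

    def test_detected_sites_stay_occupied(self):
        data, covs, spec, _ = occupancy_dataset(0.6, 0.5, 100, seed=5)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(2), pilot=True)
        det = data.detected_anywhere("sp")
        for _ in range(30):
            s.sweep()
            assert (s.z["sp"][det] == 1).all()

    def test_symmetric_coin_when_undetectable(self):
        data, covs, spec = all_zero_dataset(OCCUPANCY, 4000, J=2)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(3), pilot=True)
        set_intercept(s, ("sp", STATE), 0.0)       # psi = 0.5
        set_intercept(s, ("sp", DETECTION), -40.0)  # p ~ 0
        s.update_latent_z("sp")
        assert s.z["sp"].mean() == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(4000))


class TestLatentN:
    def test_prior_poisson_when_undetectable(self):
        data, covs, spec = all_zero_dataset(ABUNDANCE_RN, 10000, J=3)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(0), pilot=True)
        lam = 1.3
        set_intercept(s, ("sp", STATE), np.log(lam))
        set_intercept(s, ("sp", DETECTION), -40.0)
        s.update_latent_N("sp")
        draws = s.N["sp"]
        kmax = 8
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax), lam)
        exp = np.append(exp, 1 - exp.sum()) * draws.size
        chi2 = stats.chisquare(obs, exp)
        assert chi2.pvalue > 0.01

    def test_detection_forces_presence(self):
        data, covs, spec, _ = rn_dataset(1.0, 0.4, 150, seed=6)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(5), pilot=True)
        det = data.detected_anywhere("sp")
        for _ in range(30):
            s.sweep()
            assert (s.N["sp"][det] >= 1).all()

    def _two_species_sampler(self, c, n_sites=3000, seed=7):
        """RN source 'a' (never detected, r~0) feeding RN target 'b' with all
        three occasions detected; every site is an i.i.d. replicate."""
        design = make_design(n_sites, 3)
        ya = np.zeros((n_sites, 3), np.int8)
        yb = np.ones((n_sites, 3), np.int8)
        data = DetectionData(histories={"a": ya, "b": yb}, design=design)
        covs = CovariateTable(continuous={}, binary={})
        spec = ModelSpec(
            species=["a", "b"],
            submodel_of_species={"a": ABUNDANCE_RN, "b": ABUNDANCE_RN},
            state_covariates={}, detection_covariates={},
            interactions=[Interaction("a", LATENT_N, "b", STATE)],
            selection_enabled=False, random_intercepts=False)
        s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(seed), pilot=True)
        set_intercept(s, ("a", STATE), np.log(1.0))
        set_intercept(s, ("a", DETECTION), -40.0)
        set_intercept(s, ("b", STATE), np.log(0.5))
        set_intercept(s, ("b", DETECTION), 0.0)
        bb = s.blocks[("b", STATE)]
        bb.beta[0] = c
        bb.eta = s._compute_eta(bb)
        s._refresh(bb)
        return s

    def enumerate_conditional(self, c, N_b, lam_a=1.0, int_b=np.log(0.5), n_top=60):
        ns = np.arange(n_top + 1)
        logw = stats.poisson.logpmf(ns, lam_a)
        logw += stats.poisson.logpmf(N_b, np.exp(int_b + c * ns))
        w = np.exp(logw - logw.max())
        return w / w.sum()

    def test_downstream_term_matches_enumeration(self):
        c = 0.5
        s = self._two_species_sampler(c)
        N_b = int(s.N["b"][0])
        assert (s.N["b"] == N_b).all()  # identical sites -> identical init
        s.update_latent_N("a")
        draws = s.N["a"]
        pmf = self.enumerate_conditional(c, N_b)
        kmax = 7
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        exp = np.append(pmf[:kmax], pmf[kmax:].sum()) * draws.size
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_positive_downstream_effect_shifts_mass_up(self):
        # enumeration oracle: a positive effect on a well-detected downstream
        # species pulls the conditional above the plain Poisson prior mean,
        # and the bulk of the mass (low quantiles) moves up
        pmf = self.enumerate_conditional(0.5, N_b=2)
        base = stats.poisson.pmf(np.arange(pmf.size), 1.0)
        base /= base.sum()
        assert (np.arange(pmf.size) * pmf).sum() > 1.0
        assert (np.cumsum(pmf)[:3] < np.cumsum(base)[:3]).all()
        assert pmf[0] < base[0]
        # and the sampler tracks it
        s = self._two_species_sampler(0.5)
        s.update_latent_N("a")
        assert s.N["a"].mean() > 1.05


def one_covariate_selection_sampler(pseudo_loc=0.0, pseudo_scale=1.0, V=1.0,
                                    seed=8, n_sites=50):
    data, covs, spec = all_zero_dataset(
        OCCUPANCY, n_sites, J=2, extra_covs={"x": np.zeros(n_sites)},
        selection=True)
    pseudo = PseudoPrior(loc={"sp.state.x": pseudo_loc},
                         scale={"sp.state.x": pseudo_scale})
    s = GibbsSampler(data, covs, spec, rng=np.random.default_rng(seed),
                     pseudo=pseudo)
    b = s.blocks[("sp", STATE)]
    b.V = V
    return s, b


class TestBetaUpdate:
    def test_excluded_coefficient_samples_pseudo_prior(self):
        s, b = one_covariate_selection_sampler(pseudo_loc=0.3, pseudo_scale=0.7)
        b.w[0] = 0
        b.eta = s._compute_eta(b)
        s._refresh(b)
        draws = np.empty(4000)
        for i in range(draws.size):
            s.update_beta(("sp", STATE), 0)
            draws[i] = b.beta[0]
        assert stats.kstest(draws, "norm", args=(0.3, 0.7)).pvalue > 0.001

    def test_flat_likelihood_targets_slab_prior(self):
        # covariate identically zero -> likelihood flat in beta; the chain's
        # stationary law must be the slab N(0, V/m) with m = 1
        s, b = one_covariate_selection_sampler(V=2.0)
        b.scale[0] = 1.5
        draws = []
        for i in range(30000):
            s.update_beta(("sp", STATE), 0)
            if i % 15 == 14:
                draws.append(b.beta[0])
        ks = stats.kstest(np.array(draws), "norm", args=(0.0, np.sqrt(2.0)))
        assert ks.pvalue > 0.001

    def test_adaptation_hits_target_acceptance_band(self):
        data, covs, spec, _ = rn_dataset(1.0, 0.4, 200, seed=9,
                                         covariates=["x"], betas={"x": 0.5})
        s = GibbsSampler(data, covs, replace_selection(spec, False),
                         rng=np.random.default_rng(10), pilot=True)
        s.run(n_burnin=600, n_iter=400)
        rates = s.acceptance_rates()
        assert rates and all(0.2 <= r <= 0.6 for r in rates.values())


class TestInclusionUpdate:
    def test_symmetric_odds_give_half(self):
        # flat likelihood and pseudo-prior identical to the slab: the GVS
        # odds reduce to the Bernoulli(0.5) prior
        s, b = one_covariate_selection_sampler(V=1.0, pseudo_scale=1.0)
        w = np.empty(8000)
        for i in range(w.size):
            s.update_beta(("sp", STATE), 0)
            s.update_inclusion(("sp", STATE), 0)
            w[i] = b.w[0]
        assert w.mean() == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(w.size))

    def test_strong_effect_selected_null_not(self):
        data, covs, spec, _ = rn_dataset(
            0.9, 0.35, 400, seed=11, covariates=["strong", "null"],
            betas={"strong": 1.0, "null": 0.0}, selection=True)
        cfg_p = McmcConfig(n_burnin=300, n_iter=300, n_chains=1, seed=1)
        _, pseudo = run_pilot(data, covs, spec, cfg_p)
        draws = run_selection(data, covs, spec,
                              McmcConfig(n_burnin=600, n_iter=1200, n_chains=1,
                                         seed=2), pseudo)
        w_strong = draws.pooled("w:sp.state.strong").mean()
        w_null = draws.pooled("w:sp.state.null").mean()
        assert w_strong > 0.9
        assert w_null < w_strong


class TestSharedVariance:
    def test_prior_draw_when_nothing_included(self):
        s, b = one_covariate_selection_sampler()
        b.w[0] = 0
        draws = np.empty(5000)
        for i in range(draws.size):
            s.update_shared_variance(("sp", STATE))
            draws[i] = b.V
        # 1/V ~ Gamma(a, rate=b)  <=>  V ~ InvGamma(a, scale=b)
        ks = stats.kstest(draws, stats.invgamma(IG_SHAPE, scale=IG_RATE).cdf)
        assert ks.pvalue > 0.001

    def test_conditional_shape_with_one_zero_beta(self):
        # m=1, beta=0: conditional is InvGamma(a + 1/2, scale=b)
        s, b = one_covariate_selection_sampler()
        b.w[0] = 1
        b.beta[0] = 0.0
        draws = np.empty(5000)
        for i in range(draws.size):
            s.update_shared_variance(("sp", STATE))
            draws[i] = b.V
        ks = stats.kstest(draws, stats.invgamma(IG_SHAPE + 0.5, scale=IG_RATE).cdf)
        assert ks.pvalue > 0.001


class TestRandomIntercepts:
    def test_sd_recovery_across_replicates(self):
        # 8 arrays x 35 sites, true array sd = 0.5 on the occupancy logit
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            design = make_design(280, 3, n_arrays=8)
            alpha = rng.normal(0, 0.5, 8)
            psi = expit(0.2 + alpha[design.array_of_site])
            z = (rng.random(280) < psi).astype(int)
            y = ((rng.random((280, 3)) < 0.45) & (z[:, None] == 1)).astype(np.int8)
            data = DetectionData(histories={"sp": y}, design=design)
            spec = ModelSpec(species=["sp"], submodel_of_species={"sp": OCCUPANCY},
                             state_covariates={"sp": []},
                             detection_covariates={"sp": []},
                             selection_enabled=False, random_intercepts=True)
            draws, _ = run_pilot(data, CovariateTable(continuous={}, binary={}),
                                 spec, McmcConfig(n_burnin=300, n_iter=600,
                                                  n_chains=1, seed=rep))
            sd = draws.pooled("sd_array:sp.state")
            lo, hi = np.quantile(sd, [0.025, 0.975])
            hits += lo <= 0.5 <= hi
        assert hits >= 7

    def test_single_array_still_runs(self):
        data, covs, spec, _ = occupancy_dataset(0.5, 0.4, 40, seed=12)
        spec.random_intercepts = True
        draws, _ = run_pilot(data, covs, spec,
                             McmcConfig(n_burnin=50, n_iter=100, n_chains=1, seed=0))
        assert "sd_array:sp.state" in draws.names


class TestFullFits:
    def test_pilot_recovers_occupancy_grid_posterior(self):
        data, covs, spec, _ = occupancy_dataset(0.6, 0.4, 500, seed=13)
        draws, _ = run_pilot(data, covs, spec,
                             McmcConfig(n_burnin=400, n_iter=1600, n_chains=2, seed=3))
        bs = draws.pooled("sp.state.(Intercept)")
        bd = draws.pooled("sp.detection.(Intercept)")
        # oracle: quadrature over the 2-parameter posterior on a fine grid
        d = data.detections("sp")
        nd = np.bincount(d, minlength=4)
        g = np.linspace(-3, 3, 601)
        BS, BD = np.meshgrid(g, g, indexing="ij")
        psi, p = expit(BS), expit(BD)
        ll = nd[0] * np.log(psi * (1 - p) ** 3 + 1 - psi)
        for k in (1, 2, 3):
            ll += nd[k] * (np.log(psi) + k * np.log(p) + (3 - k) * np.log(1 - p))
        w = np.exp(ll - ll.max())
        w /= w.sum()
        mean_bs = (w * BS).sum()
        mean_bd = (w * BD).sum()
        assert bs.mean() == pytest.approx(mean_bs, abs=0.06)
        assert bd.mean() == pytest.approx(mean_bd, abs=0.06)
        # truth within 3 posterior sd
        assert abs(bs.mean() - logit(0.6)) < 3 * bs.std()
        assert abs(bd.mean() - logit(0.4)) < 3 * bd.std()

    def test_selection_disabled_matches_pilot_posterior(self):
        data, covs, spec, _ = rn_dataset(1.2, 0.4, 250, seed=14,
                                         covariates=["x"], betas={"x": 0.6})
        spec.selection_enabled = False
        cfg = McmcConfig(n_burnin=400, n_iter=1200, n_chains=2, seed=4)
        pil, _ = run_pilot(data, covs, spec, cfg)
        sel = run_selection(data, covs, spec, cfg, pseudo=None)
        for name in ("sp.state.(Intercept)", "sp.state.x"):
            a, b = pil.pooled(name), sel.pooled(name)
            lo_a, hi_a = np.quantile(a, [0.05, 0.95])
            lo_b, hi_b = np.quantile(b, [0.05, 0.95])
            assert max(lo_a, lo_b) < min(hi_a, hi_b)  # overlapping CRIs
            assert abs(a.mean() - b.mean()) < 3 * (a.std() + b.std()) / 2

    def test_all_zero_species_fits_with_negligible_detection(self):
        # lambda and r are only jointly identified from an all-zero history:
        # the posterior must put the implied species-level detection
        # probability near zero, whichever of the two parameters absorbs it
        data, covs, spec = all_zero_dataset(ABUNDANCE_RN, 100, J=3)
        draws, _ = run_pilot(data, covs, spec,
                             McmcConfig(n_burnin=200, n_iter=400, n_chains=1, seed=5))
        lam = np.exp(draws.pooled("sp.state.(Intercept)"))
        r = expit(draws.pooled("sp.detection.(Intercept)"))
        p_cell = 1.0 - np.exp(-lam * r)  # Poisson-mixed detection probability
        assert p_cell.mean() < 0.1


class TestKernelConsistency:
    def test_fast_loglik_paths_match_reference_kernels(self):
        import interocc as io
        cfg = io.canid_scenario(seed=7)
        t = io.simulate(cfg)
        s = GibbsSampler(t.data, t.covariates, replace_selection(cfg.spec, False),
                         rng=np.random.default_rng(3), pilot=True)
        for _ in range(5):
            s.sweep()
        rng = np.random.default_rng(0)
        for (sp, param), b in s.blocks.items():
            eta = b.eta + rng.normal(0, 0.3, b.eta.size)
            fast = s._loglik_sites(b, eta)
            ref = {
                "rn_state": lambda: L.rn_state_loglik_sites(s.N[sp], eta),
                "rn_det": lambda: L.rn_detection_loglik_sites(s.N[sp], s.d[sp],
                                                              s.J, eta),
                "occ_state": lambda: L.occ_state_loglik_sites(s.z[sp], eta),
                "occ_det": lambda: L.occ_detection_loglik_sites(s.z[sp], s.d[sp],
                                                                s.J, eta),
            }[b.kind]()
            np.testing.assert_allclose(fast, ref, atol=1e-10)


class TestPriorRecovery:
    def test_successive_conditional_keeps_prior_stationary(self):
        # Geweke-style check on a 4-site occupancy toy: alternating
        # "simulate data | theta" and "MCMC update theta | data" must leave
        # the Uniform(-10, 10) prior invariant for the intercepts.
        n, J = 4, 2
        design = make_design(n, J)
        covs = CovariateTable(continuous={}, binary={})
        spec = ModelSpec(species=["sp"], submodel_of_species={"sp": OCCUPANCY},
                         state_covariates={"sp": []}, detection_covariates={"sp": []},
                         selection_enabled=False, random_intercepts=False)
        rng = np.random.default_rng(77)
        theta = np.array([0.0, 0.0])
        kept = []
        for it in range(3000):
            psi, p = expit(theta)
            z = (rng.random(n) < psi).astype(int)
            y = ((rng.random((n, J)) < p) & (z[:, None] == 1)).astype(np.int8)
            data = DetectionData(histories={"sp": y}, design=design)
            s = GibbsSampler(data, covs, spec, rng=rng, pilot=True)
            for key, v in zip(((("sp", STATE)), (("sp", DETECTION))), theta):
                b = s.blocks[key]
                b.intercept = v
                b.scale_int = 4.0
                b.eta = s._compute_eta(b)
                s._refresh(b)
            for _ in range(6):
                s.sweep()
            theta = np.array([s.blocks[("sp", STATE)].intercept,
                              s.blocks[("sp", DETECTION)].intercept])
            if it >= 200 and it % 10 == 9:
                kept.append(theta.copy())
        kept = np.array(kept)
        for j in range(2):
            ks = stats.kstest(kept[:, j], stats.uniform(-10, 20).cdf)
            assert ks.pvalue > 0.001
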