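"""Likelihood components for the Royle-Nichols and occupancy submodels.

Two observation models share the package:

* Royle-Nichols (RN): site abundance N_i ~ Poisson(lambda_i); each of the N_i
  individuals is detected independently with per-occasion probability r, so a
  species-level detection occurs with p = 1 - (1 - r)^N.
* Single-species occupancy: occurrence z_i ~ Bernoulli(psi_i), detections
  y_ij ~ Bernoulli(p_ij * z_i).

Parameters sit on link scales (log for lambda, logit for r, p, psi) as linear
combinations of site covariates, array random intercepts, and -- for species
with inbound interaction edges -- the realized latent abundance or occurrence
of other species.  This module is pure computation: the marginal site
log-likelihoods here serve as oracles and diagnostics, while the sampler works
with the latent states directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln, logsumexp

from .data import MISSING, LATENT_N, CovariateTable


@dataclass
class LinearPredictorSpec:
    """One linear predictor on its link scale.

    ``coefficients`` covers both ordinary covariates (keyed by covariate name)
    and interaction terms (keyed by the edge label ``int:<source>``).  A
    coefficient whose ``inclusion`` entry is 0 contributes nothing, mirroring
    the variable-selection indicator w_k multiplying each term.
    """

    intercept: float
    coefficients: dict = field(default_factory=dict)
    inclusion: dict = field(default_factory=dict)
    link: str = "logit"  # "log" for lambda, "logit" for r, p, psi
    random_intercept_by_array: dict = field(default_factory=dict)

    def weight(self, name: str) -> float:
        return self.coefficients.get(name, 0.0) * self.inclusion.get(name, 1)


@dataclass
class LatentState:
    """Realized latent states: N per RN species, z per occupancy species."""

    N: dict = field(default_factory=dict)
    z: dict = field(default_factory=dict)


def rn_cell_prob(r, N):
    """Detection probability 1 - (1 - r)^N under the Royle-Nichols model.

    Computed as ``-expm1(N * log1p(-r))`` so small r with large N does not
    lose precision.  ``r`` and ``N`` broadcast.
    """
    r = np.asarray(r, dtype=float)
    N = np.asarray(N)
    if np.any(N < 0):
        raise ValueError("abundance N must be non-negative")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("individual detection probability r must be in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(N * np.log1p(-r))
    # r == 1 gives log1p(-r) = -inf; 0 * -inf is nan, but the probability is
    # 1 for N >= 1 and 0 for N == 0.
    out = np.where((r == 1.0) & (N > 0), 1.0, out)
    out = np.where(N == 0, 0.0, out)
    return out if out.shape else float(out)


def poisson_truncation_bound(lam: float, tail_tol: float = 1e-6, floor: int = 20) -> int:
    """Smallest N_max (>= floor) with upper Poisson tail mass < tail_tol."""
    n = int(stats.poisson.isf(tail_tol, max(lam, 1e-12)))
    return max(floor, n + 1)


def rn_site_loglik(y_site, r_site, lam: float, n_max: int | None = None,
                   tail_tol: float = 1e-6) -> float:
    """Marginal RN log-likelihood of one site's history, latent N summed out.

    log sum_{N=0}^{N_max} Poisson(N; lam) prod_j Bernoulli(y_j; 1-(1-r_j)^N),
    skipping missing occasions.  ``n_max`` defaults to the smallest truncation
    with Poisson tail mass below ``tail_tol``; an explicit ``n_max`` below that
    bound is an error.
    """
    y = np.asarray(y_site)
    r = np.asarray(r_site, dtype=float)
    obs = y != MISSING
    y, r = y[obs].astype(float), r[obs]
    required = poisson_truncation_bound(lam, tail_tol)
    if n_max is None:
        n_max = required
    elif n_max < required:
        raise ValueError(f"n_max={n_max} leaves Poisson tail mass >= {tail_tol}; "
                         f"need n_max >= {required}")
    ns = np.arange(n_max + 1)
    log_prior = stats.poisson.logpmf(ns, lam)
    p = rn_cell_prob(r[None, :], ns[:, None])  # (n_max+1, J)
    with np.errstate(divide="ignore"):
        log_obs = np.where(y[None, :] == 1, np.log(p), np.log1p(-p)).sum(axis=1)
    return float(logsumexp(log_prior + log_obs))


def occ_site_loglik(y_site, p_site, psi: float) -> float:
    """Occupancy log-likelihood of one site's history, z summed out.

    log[ psi * prod_j p_j^y_j (1-p_j)^(1-y_j) + (1-psi) * I(all y_j == 0) ],
    skipping missing occasions.
    """
    y = np.asarray(y_site)
    p = np.asarray(p_site, dtype=float)
    obs = y != MISSING
    y, p = y[obs].astype(float), p[obs]
    with np.errstate(divide="ignore"):
        log_det = np.where(y == 1, np.log(p), np.log1p(-p)).sum()
    if (y == 1).any():
        return float(np.log(psi) + log_det if psi > 0 else -np.inf)
    terms = []
    if psi > 0:
        terms.append(np.log(psi) + log_det)
    if psi < 1:
        terms.append(np.log1p(-psi))
    return float(logsumexp(terms))


def build_predictor(spec: LinearPredictorSpec, covs: CovariateTable,
                    latents: LatentState, interactions: list, site: int,
                    array_of_site=None) -> float:
    """Evaluate one site's linear predictor on the link scale.

    intercept + array random intercept + sum_k w_k beta_k X_ki over covariates
    + sum over inbound interaction edges of w_e beta_e times the source
    species' realized latent value at the site.  Interaction terms carry
    inclusion indicators exactly like ordinary covariates.
    """
    eta = spec.intercept
    if spec.random_intercept_by_array and array_of_site is not None:
        eta += spec.random_intercept_by_array.get(int(array_of_site[site]), 0.0)
    for name, beta in spec.coefficients.items():
        if name.startswith("int:"):
            continue
        eta += spec.inclusion.get(name, 1) * beta * covs.column(name)[site]
    for edge in interactions:
        store = latents.N if edge.source_quantity == LATENT_N else latents.z
        if edge.source not in store:
            raise KeyError(f"latent value for interaction source {edge.source!r} "
                           "not realized; update species in topological order")
        eta += spec.weight(edge.label()) * store[edge.source][site]
    return float(eta)


def inverse_link(eta, link: str):
    if link == "log":
        return np.exp(eta)
    if link == "logit":
        return expit(eta)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# vectorized site-conditional log-likelihood kernels used by the sampler
# ---------------------------------------------------------------------------
# Sufficient statistics: with site-level parameters, a site's RN detection
# likelihood depends on its history only through d (detections) and J (active
# occasions): p^... -> d*log(p) + (J-d)*N*log1p(-r).


def rn_state_loglik_sites(N, eta):
    """Poisson log-pmf of latent N given log-lambda = eta, per site."""
    return N * eta - np.exp(eta) - gammaln(N + 1.0)


def rn_detection_loglik_sites(N, d, J, eta):
    """RN detection log-likelihood per site given latent N and logit-r = eta."""
    log1mr = -np.logaddexp(0.0, eta)  # log(1 - expit(eta))
    log_miss = N * log1mr  # log (1-r)^N = log(1-p)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.log(-np.expm1(log_miss))
        ll = np.where(d > 0, d * log_p, 0.0) + (J - d) * log_miss
    # N == 0 with d > 0 is impossible (likelihood zero)
    return np.where((N == 0) & (d > 0), -np.inf, ll)


def occ_state_loglik_sites(z, eta):
    """Bernoulli log-pmf of occurrence z given logit-psi = eta, per site."""
    return z * eta - np.logaddexp(0.0, eta)


def occ_detection_loglik_sites(z, d, J, eta):
    """Occupancy detection log-likelihood per site given z and logit-p = eta."""
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return z * (d * log_p + (J - d) * log_q)
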