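import numpy as np
import pytest

from interocc.data import (ABUNDANCE_RN, OCCUPANCY, CovariateTable,
                           DetectionData, ModelSpec, SurveyDesign)


def make_design(n_sites, n_occasions=3, n_arrays=1, active=None, rng=None):
    """Single- or multi-array design with optional explicit activity mask."""
    if active is None:
        active = np.ones((n_sites, n_occasions), dtype=bool)
    per = n_sites // n_arrays
    arr = np.minimum(np.arange(n_sites) // per, n_arrays - 1)
    return SurveyDesign(site_labels=tuple(f"s{i + 1}" for i in range(n_sites)),
                        array_of_site=arr,
                        array_names=tuple(f"A{a + 1}" for a in range(n_arrays)),
                        active=active)


def occupancy_dataset(psi, p, n_sites, n_occasions=3, seed=0, n_arrays=1):
    """Single-species occupancy data with known truth."""
    rng = np.random.default_rng(seed)
    design = make_design(n_sites, n_occasions, n_arrays)
    z = (rng.random(n_sites) < psi).astype(int)
    y = ((rng.random((n_sites, n_occasions)) < p) & (z[:, None] == 1)).astype(np.int8)
    data = DetectionData(histories={"sp": y}, design=design)
    spec = ModelSpec(species=["sp"], submodel_of_species={"sp": OCCUPANCY},
                     state_covariates={"sp": []}, detection_covariates={"sp": []},
                     selection_enabled=False, random_intercepts=False)
    return data, CovariateTable(continuous={}, binary={}), spec, z


def rn_dataset(lam, r, n_sites, n_occasions=3, seed=0, covariates=None,
               betas=None, selection=False):
    """Single-species Royle-Nichols data; optional standardized covariates on
    log-lambda with true coefficients ``betas``."""
    rng = np.random.default_rng(seed)
    design = make_design(n_sites, n_occasions)
    covs = {}
    eta = np.full(n_sites, np.log(lam))
    if covariates:
        for name in covariates:
            x = rng.normal(0, 1, n_sites)
            x = (x - x.mean()) / x.std() * 0.5
            covs[name] = x
            eta = eta + betas.get(name, 0.0) * x
    N = rng.poisson(np.exp(eta))
    p = 1.0 - (1.0 - r) ** N
    y = (rng.random((n_sites, n_occasions)) < p[:, None]).astype(np.int8)
    data = DetectionData(histories={"sp": y}, design=design)
    spec = ModelSpec(species=["sp"], submodel_of_species={"sp": ABUNDANCE_RN},
                     state_covariates={"sp": list(covs)},
                     detection_covariates={"sp": []},
                     selection_enabled=selection, random_intercepts=False)
    return data, CovariateTable(continuous=covs, binary={}), spec, N


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
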