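import numpy as np
import pytest

import sekrige as sk


@pytest.fixture(scope="session")
def malawi_params() -> sk.GenerativeParams:
    """Generative parameters at the scale of the national survey fit."""
    return sk.GenerativeParams.malawi_like()


@pytest.fixture(scope="session")
def small_table(malawi_params):
    """A small nested survey (8 clusters x 3 households x 2 individuals)."""
    design = sk.generate_design(
        n_clusters=8,
        urban_fraction=0.25,
        households_per_cluster=3,
        individuals_per_household=2,
        seed=11,
    )
    return sk.simulate_survey(design, malawi_params, seed=12)


def plugin_model(params: sk.GenerativeParams, n_obs: int = 0) -> sk.FittedModel:
    """FittedModel carrying known (plug-in) parameters, for kriging/CV tests
    that do not need an actual REML fit."""
    return sk.FittedModel(
        mu_hat=params.mu,
        components=params.components,
        matern=params.matern,
        reml_loglik=0.0,
        n_obs=n_obs,
        converged=True,
    )


def dense_reml_loglik(y, index, components, matern):
    """Brute-force REML log-likelihood via the dense covariance matrix."""
    V = sk.assemble_covariance(
        index.cl_codes, index.hh_codes, components, matern, index.cluster_coords
    )
    n = len(y)
    one = np.ones(n)
    Vi = np.linalg.inv(V)
    q11 = one @ Vi @ one
    q1y = one @ Vi @ y
    qyy = y @ Vi @ y
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    return -0.5 * (
        (n - 1) * np.log(2 * np.pi) + logdet + np.log(q11) + qyy - q1y**2 / q11
    )
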