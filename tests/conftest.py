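"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from mixglm import MixtureGLM, MixtureGLMParams, get_family
from mixglm.model import MixtureGLMResults

FAMILY_NAMES = ["gaussian", "poisson", "binomial"]
TRIALS = 10  # binomial trials used throughout the tests


def family_for(name):
    return get_family(name, trials=TRIALS if name == "binomial" else None)


def random_instance(name, rng, n=None, k=2):
    """A small random data set plus arbitrary (not fitted) mixture parameters
    and a random soft partition — a generic evaluation point for the
    deviance machinery."""
    n = n or int(rng.integers(8, 21))
    x = rng.standard_normal(n)
    beta = rng.normal(0.0, 0.7, size=(k, 2))
    fam = family_for(name)
    eta = beta[:, 0][None, :] + x[:, None] * beta[:, 1][None, :]
    if name == "gaussian":
        phi = rng.uniform(0.3, 2.0, size=k)
        comp = rng.integers(0, k, size=n)
        y = rng.normal(eta[np.arange(n), comp], np.sqrt(phi[comp]))
    elif name == "poisson":
        phi = np.ones(k)
        comp = rng.integers(0, k, size=n)
        y = rng.poisson(np.exp(eta[np.arange(n), comp])).astype(float)
    else:
        phi = np.ones(k)
        comp = rng.integers(0, k, size=n)
        p = 1.0 / (1.0 + np.exp(-eta[np.arange(n), comp]))
        y = rng.binomial(TRIALS, p).astype(float)
    pi = rng.dirichlet(np.full(k, 5.0))
    params = MixtureGLMParams(pi=pi, beta=beta, phi=phi, family=fam)
    z = rng.dirichlet(np.ones(k), size=n)
    model = MixtureGLM(y, x, k=k, family=fam)
    return model, params, z


def fitted_instance(name, rng, n=None, k=2):
    """Random small data with a random soft partition and the M-step-fitted
    parameters under it: the component means are then the weighted-GLM
    optimum for the given posteriors (which the Gaussian explained-deviance
    closed form requires), while nothing is an EM fixed point."""
    from mixglm.exceptions import MixGLMError

    while True:
        model, _, z = random_instance(name, rng, n=n, k=k)
        try:
            params = model.m_step(z)
        except MixGLMError:
            continue
        return model, params, z


def results_at(model, params, z):
    """Wrap an arbitrary evaluation point (params, posteriors) in a results
    object without running EM."""
    ll = model.loglike(params)
    return MixtureGLMResults(model, params, np.asarray(z, dtype=float),
                             np.array([ll]), True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
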