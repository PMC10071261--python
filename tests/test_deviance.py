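"""Deviance decompositions: closed forms, identities, R2 measures."""

import numpy as np
import pytest

from mixglm import (
    MixtureGLM,
    adjusted_r2,
    condition,
    decompose,
    generate_dataset,
    weighted_loglik,
)
from mixglm.deviance import local_deviance_components
from mixglm.exceptions import BoundaryError

from conftest import family_for, fitted_instance, random_instance, results_at


def _loglik_deviances(res):
    """Independent oracle: each local deviance as twice a difference of
    weighted log-likelihoods under the exact densities."""
    model = res.model
    fam = model.family
    y = model.endog
    out = {"D": [], "RD": [], "ED": [], "BD_j": []}
    for j in range(res.k):
        w = res.posteriors[:, j]
        phi = res.params.phi[j]
        ybar_j = np.full(model.n, res.soft_means[j])
        ybar = np.full(model.n, res.grand_mean)
        mu = res.fitted_means[:, j]
        ll = lambda m: weighted_loglik(y, m, phi, w, fam)
        sat = ll(y)
        out["D"].append(2 * (sat - ll(ybar_j)))
        out["RD"].append(2 * (sat - ll(mu)))
        out["ED"].append(2 * (ll(mu) - ll(ybar_j)))
        out["BD_j"].append(2 * (ll(ybar_j) - ll(ybar)))
    return {k: np.array(v) for k, v in out.items()}


@pytest.mark.parametrize("name", ["gaussian", "poisson", "binomial"])
def test_closed_forms_equal_loglik_differences(name, rng):
    """Family closed forms match 2x weighted log-likelihood differences at
    arbitrary soft partitions (component means M-step-fitted under them)."""
    for _ in range(10):
        model, params, z = fitted_instance(name, rng)
        res = results_at(model, params, z)
        comp = local_deviance_components(res)
        oracle = _loglik_deviances(res)
        for key in ("D", "RD", "ED", "BD_j"):
            np.testing.assert_allclose(
                comp[key], oracle[key], rtol=1e-8, atol=1e-8,
                err_msg=f"{name}:{key}",
            )


def test_gaussian_generic_path_equals_sum_of_squares(rng):
    """The likelihood-difference route reduces to the weighted
    sum-of-squares formulas for the Gaussian family."""
    model, params, z = random_instance("gaussian", rng)
    res = results_at(model, params, z)
    oracle = _loglik_deviances(res)
    y = model.endog[:, None]
    ss_D = np.sum(z * (y - res.soft_means) ** 2, axis=0) / params.phi
    np.testing.assert_allclose(oracle["D"], ss_D, rtol=1e-9)


def test_poisson_toy_frozen_values():
    """y = (0, 2), unit memberships, fitted means (0.5, 1.5):
    D = 4 ln 2, RD = 4 ln(4/3), ED = 4 ln(3/2) from the count closed forms."""
    y = np.array([0.0, 2.0])
    x = np.array([0.0, 1.0])
    model = MixtureGLM(y, x, k=1, family="poisson")
    from mixglm import MixtureGLMParams

    params = MixtureGLMParams(
        pi=np.array([1.0]),
        beta=np.array([[np.log(0.5), np.log(3.0)]]),  # means 0.5, 1.5
        phi=np.array([1.0]),
        family=family_for("poisson"),
    )
    res = results_at(model, params, np.ones((2, 1)))
    comp = local_deviance_components(res)
    assert comp["D"][0] == pytest.approx(4 * np.log(2), rel=1e-12)
    assert comp["RD"][0] == pytest.approx(4 * np.log(4 / 3), rel=1e-12)
    assert comp["ED"][0] == pytest.approx(4 * np.log(3 / 2), rel=1e-12)


def test_perfect_local_fit_has_zero_residual_deviance():
    """Exact within-cluster lines: RD_j = 0 and ED_j = D_j."""
    x = np.concatenate([np.linspace(-1, 1, 10)] * 2)
    y = np.concatenate([-2.0 + 0.5 * x[:10], 2.0 - 0.5 * x[10:]])
    labels = np.repeat([1, 2], 10)
    model = MixtureGLM(y, x, k=2, family="gaussian")
    res = model.fit(init=labels, max_iter=0)
    comp = local_deviance_components(res)
    np.testing.assert_allclose(comp["RD"], 0.0, atol=1e-10)
    np.testing.assert_allclose(comp["ED"], comp["D"], rtol=1e-10)


def test_equal_soft_means_give_zero_between_deviance(rng):
    """Uniform posteriors force ybar_1 = ybar_2 = ybar, hence BD = NBD = 0."""
    model, _, _ = random_instance("gaussian", rng, n=30)
    params = model.m_step(np.full((model.n, 2), 0.5))
    res = results_at(model, params, np.full((model.n, 2), 0.5))
    dec = decompose(res)
    assert dec.BD == pytest.approx(0.0, abs=1e-12)
    assert dec.nbd == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("name", ["gaussian", "poisson", "binomial"])
def test_decomposition_identities_at_fits(name, rng):
    """D_j = ED_j + RD_j; TD = BD + EWD + RWD; shares sum to one;
    R2 is the weighted mean of local R2; everything in range at ML fits."""
    cond = condition(name, 3)
    for seed in range(5):
        data = generate_dataset(cond, seed=seed)
        model = MixtureGLM.from_data(data, k=2, family=name, trials=cond.m)
        res = model.fit(init=data.true_labels)
        dec = res.deviance()
        np.testing.assert_allclose(dec.D, dec.ED + dec.RD,
                                   rtol=1e-8, atol=1e-8)
        assert dec.TD == pytest.approx(dec.BD + dec.EWD + dec.RWD, rel=1e-8)
        assert dec.nbd + dec.newd + dec.nrwd == pytest.approx(1.0, abs=1e-10)
        assert dec.ned == pytest.approx(1.0 - dec.nrwd, abs=1e-12)
        assert dec.r2 == pytest.approx(np.sum(dec.weights * dec.r2_local),
                                       abs=1e-10)
        assert np.all(dec.D >= -1e-8) and np.all(dec.ED >= -1e-8)
        assert np.all((dec.r2_local >= 0) & (dec.r2_local <= 1))
        assert 0.0 <= dec.r2 <= 1.0


@pytest.mark.parametrize("name", ["poisson", "binomial"])
def test_total_deviance_is_partition_free(name, rng):
    """For one-parameter families the total deviance collapses to a
    partition-free sum, so different fits of the same data share TD."""
    cond = condition(name, 4)
    data = generate_dataset(cond, seed=11)
    m2 = MixtureGLM.from_data(data, k=2, family=name, trials=cond.m)
    td_a = m2.fit(init=data.true_labels).deviance().TD
    td_b = m2.fit(init="kmeans", seed=3).deviance().TD
    m1 = MixtureGLM.from_data(data, k=1, family=name, trials=cond.m)
    td_c = m1.fit().deviance().TD
    assert td_a == pytest.approx(td_b, rel=1e-10)
    assert td_a == pytest.approx(td_c, rel=1e-10)


@pytest.mark.parametrize("name", ["gaussian", "poisson", "binomial"])
def test_k1_reduction_matches_single_glm_r2(name, rng):
    """k = 1: NBD = 0 and the overall R2 equals the textbook deviance R2
    (explained over null deviance) computed directly from log-likelihoods."""
    cond = condition(name, 4)
    data = generate_dataset(cond, seed=2)
    model = MixtureGLM.from_data(data, k=1, family=name, trials=cond.m)
    res = model.fit()
    dec = res.deviance()
    assert dec.nbd == 0.0
    fam = model.family
    y = model.endog
    w = np.ones(model.n)
    phi = res.params.phi[0]
    mu = res.fitted_means[:, 0]
    ybar = np.full(model.n, y.mean())
    null_dev = 2 * (weighted_loglik(y, y, phi, w, fam)
                    - weighted_loglik(y, ybar, phi, w, fam))
    expl_dev = 2 * (weighted_loglik(y, mu, phi, w, fam)
                    - weighted_loglik(y, ybar, phi, w, fam))
    assert dec.r2 == pytest.approx(expl_dev / null_dev, abs=1e-10)
    assert dec.TD == pytest.approx(dec.WD, rel=1e-12)


def test_adjusted_r2_arithmetic():
    # RD_j = 2, D_j = 10, nhat_j = 11, d = 1: 1 - (2/9)/(10/10) = 7/9
    local, overall = adjusted_r2(
        D=np.array([10.0]), RD=np.array([2.0]), WD=10.0, RWD=2.0,
        n=11, d=1, k=1, soft_sizes=np.array([11.0]),
    )
    assert local[0] == pytest.approx(7 / 9)
    # k = 1 overall reduces to the single-GLM adjusted form
    assert overall == pytest.approx(1 - (2 / 9) / (10 / 10))
    # zero residual deviance: adjusted local R2 = 1
    local, _ = adjusted_r2(np.array([5.0]), np.array([0.0]), 5.0, 0.0,
                           20, 1, 1, np.array([20.0]))
    assert local[0] == 1.0
    # nonpositive degrees of freedom flagged as NaN
    local, overall = adjusted_r2(np.array([5.0]), np.array([1.0]), 5.0, 1.0,
                                 2, 2, 1, np.array([2.0]))
    assert np.isnan(local[0]) and np.isnan(overall)


def test_degenerate_inputs_flagged(rng):
    """Constant response: TD = WD = 0, normalized fields undefined-flagged."""
    y = np.full(12, 3.0)
    x = rng.standard_normal(12)
    model = MixtureGLM(y, x, k=1, family="gaussian")
    res = model.fit()
    dec = res.deviance()
    assert np.isnan(dec.nbd) and np.isnan(dec.r2)
    assert "NBD" in dec.flags["undefined"] and "R2" in dec.flags["undefined"]


def test_all_zero_cluster_boundary_error():
    y = np.zeros(10)
    x = np.linspace(-1, 1, 10)
    model = MixtureGLM(y, x, k=1, family="poisson")
    from mixglm import MixtureGLMParams

    params = MixtureGLMParams(pi=np.array([1.0]),
                              beta=np.array([[-1.0, 0.0]]),
                              phi=np.array([1.0]),
                              family=family_for("poisson"))
    res = results_at(model, params, np.ones((10, 1)))
    with pytest.raises(BoundaryError):
        local_deviance_components(res)


def test_offset_aware_null_option(rng):
    """The optional offset-aware local null changes the decomposition but
    preserves the additive identities."""
    n = 150
    x = rng.standard_normal(n)
    off = rng.uniform(0, 2, n)
    lab = rng.integers(1, 3, n)
    eta = np.where(lab == 1, -0.5 + 0.4 * x, 1.0 - 0.3 * x) + off
    y = rng.poisson(np.exp(eta)).astype(float)
    model = MixtureGLM(y, x, k=2, family="poisson", offset=off)
    res = model.fit(init=lab)
    dec_mean = res.deviance(offset_aware_null=False)
    dec_off = res.deviance(offset_aware_null=True)
    for dec in (dec_mean, dec_off):
        assert dec.TD == pytest.approx(dec.BD + dec.EWD + dec.RWD, rel=1e-8)
    assert dec_mean.r2 != pytest.approx(dec_off.r2, abs=1e-6)
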