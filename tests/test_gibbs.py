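import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import ks_2samp, truncnorm

from pgdina import (
    ClassProbs,
    ItemParams,
    LatentClassSpace,
    PriorSpec,
    QMatrix,
    ResponseMatrix,
    ideal_response_table,
    pooled_eap,
    run_pggsa,
    sample_pg,
)
from pgdina.gibbs import (
    AugmentedState,
    PGAuxiliaries,
    class_log_weights,
    update_alpha,
    update_beta,
    update_pi,
    update_W,
    update_zeta,
)
from .oracles import direct_class_weights, toy_posterior_mean_g


def _k3_q():
    rows = [
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, 0, 1], [0, 1, 1],
        [1, 1, 0], [1, 0, 1], [0, 1, 1],
        [1, 1, 1], [1, 1, 1], [1, 1, 1],
    ]
    return QMatrix(np.array(rows))


# ---------------------------------------------------------------------------
# single-block conditionals


def test_update_zeta_prior_draw_when_no_data(rng):
    """Empty sums reduce the conditional to the N(mu_zeta, var_zeta) prior."""
    prior = PriorSpec(mu_zeta=-1.5, var_zeta=0.49)
    params = ItemParams(np.array([0.0]), np.array([1.0]))
    empty = np.empty((0,))
    draws = np.array(
        [update_zeta(0, empty, empty, empty, params, prior, rng) for _ in range(4000)]
    )
    assert draws.mean() == pytest.approx(-1.5, abs=4 * 0.7 / np.sqrt(4000))
    assert draws.std() == pytest.approx(0.7, rel=0.05)


def test_update_zeta_diffuse_limit(rng):
    """With a flat prior and eta=0 everywhere the posterior mean is
    sum(Y - 1/2) / sum(W)."""
    n = 400
    y = (rng.random(n) < 0.3).astype(float)
    w = rng.gamma(2.0, 0.1, size=n)
    prior = PriorSpec(var_zeta=1e12)
    params = ItemParams(np.array([0.0]), np.array([2.0]))
    eta = np.zeros(n)
    m_expected = (y - 0.5).sum() / w.sum()
    V = 1.0 / w.sum()
    draws = np.array(
        [update_zeta(0, y, w, eta, params, prior, rng) for _ in range(3000)]
    )
    assert draws.mean() == pytest.approx(m_expected, abs=4 * np.sqrt(V / 3000))


def test_update_beta_positive_and_prior_case(rng):
    """No eta=1 examinees: beta is drawn from its prior truncated to (0, inf)."""
    prior = PriorSpec(mu_beta=-1.0, var_beta=1.0)
    params = ItemParams(np.array([0.3]), np.array([1.0]))
    n = 200
    y = (rng.random(n) < 0.4).astype(float)
    w = rng.gamma(2.0, 0.1, size=n)
    eta = np.zeros(n)
    draws = np.array(
        [update_beta(0, y, w, eta, params, prior, rng) for _ in range(10_000)]
    )
    assert (draws > 0).all()
    # rejection-sampling oracle from the untruncated normal
    ref = rng.normal(-1.0, 1.0, size=400_000)
    ref = ref[ref > 0][: draws.size]
    stat, _ = ks_2samp(draws, ref)
    assert stat < 0.02


def test_update_W_matches_marginal_pg(rng):
    """update_W draws are marginally PG(1, |z|) at each cell."""
    Q = QMatrix([[1], [1]])
    space = LatentClassSpace(1)
    eta_tab = ideal_response_table(Q, space).astype(float)
    params = ItemParams(np.array([-1.0, 0.5]), np.array([2.0, 1.0]))
    N = 6000
    state = AugmentedState(
        params=params,
        W=PGAuxiliaries(np.ones((N, 2))),
        class_index=np.ones(N, dtype=int),  # everyone in the mastery class
        pi=ClassProbs([0.5, 0.5]),
    )
    W = update_W(state, eta_tab, rng).W
    assert (W > 0).all()
    for j, z in enumerate(params.zeta + params.beta):  # eta = 1 for all
        ref = sample_pg(float(z), rng, size=N)
        stat, _ = ks_2samp(W[:, j], ref)
        assert stat < 0.035
    # larger |z| concentrates W at smaller values
    assert W[:, 0].mean() < sample_pg(0.0, rng, size=N).mean()


def test_class_log_weights_hand_case():
    """C=2, one item: weights match a scalar hand computation."""
    params = ItemParams(np.array([-1.0]), np.array([2.0]))
    pi = ClassProbs([0.3, 0.7])
    eta = np.array([[0], [1]])
    y, w = np.array([1.0]), np.array([0.4])
    got = class_log_weights(y, w, params, eta, pi)
    k = 0.5
    want0 = np.log(0.3) + k * (-1.0) - 0.4 * 1.0 / 2
    want1 = np.log(0.7) + k * 1.0 - 0.4 * 1.0 / 2
    np.testing.assert_allclose(got, [want0, want1], atol=1e-12)
    from scipy.special import logsumexp

    assert np.exp(got - logsumexp(got)).sum() == pytest.approx(1.0, abs=1e-12)


def test_class_weights_equal_direct_evaluation(rng):
    """Simplified step-4 weights equal the unsimplified cosh-tilted form."""
    for _ in range(20):
        J = int(rng.integers(1, 5))
        K = int(rng.integers(1, 3))
        Qe = rng.integers(0, 2, size=(J, K))
        for j in range(J):
            Qe[j, rng.integers(K)] = 1  # no empty-requirement rows
        Q = QMatrix(Qe)
        space = LatentClassSpace(K)
        eta = ideal_response_table(Q, space)
        params = ItemParams(rng.normal(size=J), rng.exponential(1.5, size=J) + 0.1)
        pi = ClassProbs(rng.dirichlet(np.ones(space.C)))
        y = rng.integers(0, 2, size=J).astype(float)
        w = rng.gamma(2.0, 0.2, size=J)
        logw = class_log_weights(y, w, params, eta, pi)
        p = np.exp(logw - logw.max())
        p /= p.sum()
        ref = direct_class_weights(y, w, params.zeta, params.beta, eta, pi.pi)
        np.testing.assert_allclose(p, ref, atol=1e-10)


def test_update_alpha(rng):
    w = np.array([-np.inf, 0.0, -np.inf])
    assert all(update_alpha(0, w, rng) == 1 for _ in range(20))
    with pytest.raises(ValueError):
        update_alpha(0, np.full(3, -np.inf), rng)
    # uniform weights: chi-square goodness of fit over C=8
    draws = np.array([update_alpha(0, np.zeros(8), rng) for _ in range(8000)])
    counts = np.bincount(draws, minlength=8)
    chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
    assert chi2 < 24.3  # chi2(7) at the 0.001 level


def test_update_pi(rng):
    pi = update_pi(np.empty(0, dtype=int), 1.0, 4, rng)
    assert pi.pi.sum() == pytest.approx(1.0, abs=1e-12)
    # everyone in class 0, large N: mean of pi_0 -> (d0 + N) / (C d0 + N)
    N, C, d0 = 500, 4, 1.0
    draws = np.array(
        [update_pi(np.zeros(N, dtype=int), d0, C, rng).pi[0] for _ in range(3000)]
    )
    want = (d0 + N) / (C * d0 + N)
    assert draws.mean() == pytest.approx(want, abs=0.003)


# ---------------------------------------------------------------------------
# full sampler


def test_run_pggsa_deterministic_and_constrained(small_q, rng):
    from pgdina import SimulationCondition, generate_dataset

    cond = SimulationCondition(N=120, Q=small_q, noise="HNL")
    Y, _ = generate_dataset(cond, rng)
    a = run_pggsa(Y, small_q, n_iter=300, burn_in=100, n_chains=2, seed=7)
    b = run_pggsa(Y, small_q, n_iter=300, burn_in=100, n_chains=2, seed=7)
    for ca, cb in zip(a, b):
        np.testing.assert_array_equal(ca.zeta, cb.zeta)
        np.testing.assert_array_equal(ca.beta, cb.beta)
        np.testing.assert_array_equal(ca.pi, cb.pi)
        assert (ca.beta > 0).all()
        assert ca.n_stored == 200
        np.testing.assert_allclose(ca.pi.sum(axis=1), 1.0, atol=1e-9)
    # different seeds differ
    c = run_pggsa(Y, small_q, n_iter=300, burn_in=100, seed=8)
    assert not np.array_equal(a[0].zeta, c[0].zeta)


def test_run_pggsa_rejects_bad_settings(small_q):
    Y = ResponseMatrix(np.zeros((4, small_q.J), dtype=int))
    with pytest.raises(ValueError):
        run_pggsa(Y, small_q, n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        run_pggsa(ResponseMatrix(np.zeros((4, 3), dtype=int)), small_q)


def test_parameter_recovery_k3():
    """EAP of every intercept lands within 3 posterior SDs of the truth."""
    from pgdina import SimulationCondition, generate_dataset

    Q = _k3_q()
    cond = SimulationCondition(N=200, Q=Q, noise="LNL")
    Y, truth = generate_dataset(cond, np.random.default_rng(11))
    chains = run_pggsa(Y, Q, n_iter=2500, burn_in=1000, seed=11)
    draws = chains[0].zeta
    eap, sd = draws.mean(axis=0), draws.std(axis=0)
    assert (np.abs(eap - truth["params"].zeta) < 3 * sd).all()


def test_all_mastery_data_concentrates_pi():
    """All-correct K=1 data puts nearly all mass on the mastery class.

    All-ones data alone cannot distinguish 'everyone masters, 1-s near 1'
    from 'nobody masters, g near 1', so a moderately informative prior pins
    the guessing rate low and the posterior must attribute the data to
    mastery."""
    Q = QMatrix([[1], [1], [1], [1]])
    Y = ResponseMatrix(np.ones((100, 4), dtype=int))
    prior = PriorSpec(mu_zeta=-2.2, var_zeta=1.0, mu_beta=4.4, var_beta=1.0)
    chains = run_pggsa(Y, Q, prior=prior, n_iter=600, burn_in=200, seed=3)
    assert pooled_eap(chains)["pi"][1] > 0.9


def test_toy_posterior_matches_quadrature():
    """J=1, K=1 model: PGGSA posterior mean of g matches 3-d quadrature."""
    prior = PriorSpec(mu_zeta=0.0, var_zeta=4.0, mu_beta=1.0, var_beta=4.0)
    Q = QMatrix([[1]])
    rng = np.random.default_rng(2)
    N = 50
    alpha = rng.random(N) < 0.5
    p = np.where(alpha, 0.8, 0.2)
    Y = ResponseMatrix((rng.random(N) < p).astype(int)[:, None])
    chains = run_pggsa(Y, Q, prior=prior, n_iter=20_000, burn_in=4000, seed=2)
    g_eap = expit(chains[0].zeta[:, 0]).mean()
    want = toy_posterior_mean_g(int(Y.entries.sum()), N, prior)
    assert g_eap == pytest.approx(want, abs=0.02)


def test_joint_distribution_stationarity():
    """Geweke-style check: successive-conditional simulation preserves the
    prior marginals of (zeta, beta, pi) on a tiny K=1 model."""
    prior = PriorSpec(mu_zeta=-1.0, var_zeta=0.25, mu_beta=1.0, var_beta=0.25)
    Q = QMatrix([[1], [1], [1]])
    space = LatentClassSpace(1)
    eta_tab = ideal_response_table(Q, space).astype(float)
    N, J, C = 20, 3, 2
    T = 4000
    rng = np.random.default_rng(99)

    sd_z, sd_b = np.sqrt(prior.var_zeta), np.sqrt(prior.var_beta)
    zeta = prior.mu_zeta + sd_z * rng.standard_normal(J)
    beta = truncnorm.rvs(-prior.mu_beta / sd_b, np.inf, loc=prior.mu_beta,
                         scale=sd_b, size=J, random_state=rng)
    pi = rng.dirichlet([prior.delta0] * C)
    cls = rng.integers(0, C, size=N)

    zs, bs, ps = [], [], []
    params = ItemParams(zeta, beta)
    for _ in range(T):
        eta_i = eta_tab[cls]
        Y = (rng.random((N, J)) < expit(params.zeta + params.beta * eta_i)).astype(float)
        W = sample_pg(params.zeta[None, :] + params.beta[None, :] * eta_i, rng)
        zeta = np.array(
            [update_zeta(j, Y, W, eta_i[:, j], params, prior, rng) for j in range(J)]
        )
        params = ItemParams(zeta, params.beta)
        beta = np.array(
            [update_beta(j, Y, W, eta_i[:, j], params, prior, rng) for j in range(J)]
        )
        params = ItemParams(zeta, beta)
        pic = ClassProbs(pi)
        cls = np.array(
            [update_alpha(i, class_log_weights(Y[i], W[i], params, eta_tab, pic), rng)
             for i in range(N)]
        )
        pi = update_pi(cls, prior.delta0, C, rng).pi
        zs.append(zeta.copy())
        bs.append(beta.copy())
        ps.append(pi[1])

    zs, bs, ps = np.array(zs)[500:], np.array(bs)[500:], np.array(ps)[500:]
    beta_prior_mean = truncnorm.mean(-prior.mu_beta / sd_b, np.inf,
                                     loc=prior.mu_beta, scale=sd_b)
    assert zs.mean() == pytest.approx(prior.mu_zeta, abs=0.1)
    assert zs.var() == pytest.approx(prior.var_zeta, rel=0.25)
    assert bs.mean() == pytest.approx(beta_prior_mean, abs=0.1)
    assert ps.mean() == pytest.approx(0.5, abs=0.06)  # Beta(1,1) marginal
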