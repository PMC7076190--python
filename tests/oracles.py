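"""Independent reference implementations used only to check the package.

Everything here deliberately avoids the code paths it validates: the PG
draws come from the defining gamma series, the class weights from a direct
evaluation of the tilted-auxiliary posterior, the likelihood from naive
loops, and the item parameters from marginal-ML EM.
"""

import numpy as np


def pg_series_sampler(z, size, rng, n_terms=200):
    """PG(1, z) by truncating the defining infinite sum of gammas."""
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + z**2 / (4 * np.pi**2)  # (n_terms,)
    gam = rng.standard_gamma(1.0, size=(size, n_terms))
    return (gam / denom).sum(axis=1) / (2 * np.pi**2)


def direct_class_weights(y_i, w_i, zeta, beta, eta_table, pi):
    """Normalized class probabilities from the unsimplified posterior factors:
    pi_c * prod_j Bernoulli(y; logistic(z)) * cosh(z/2) * exp(-w z^2 / 2)."""
    C = eta_table.shape[0]
    out = np.empty(C)
    for c in range(C):
        prob = pi[c]
        for j in range(len(y_i)):
            z = zeta[j] + beta[j] * eta_table[c, j]
            p = 1.0 / (1.0 + np.exp(-z))
            bern = p if y_i[j] == 1 else 1.0 - p
            prob *= bern * np.cosh(z / 2.0) * np.exp(-w_i[j] * z**2 / 2.0)
        out[c] = prob
    return out / out.sum()


def brute_force_marginal_loglik(Y, zeta, beta, pi, Q):
    """Naive double loop over examinees and all 2^K classes."""
    N, J = Y.shape
    K = Q.shape[1]
    total = 0.0
    for i in range(N):
        acc = 0.0
        for c in range(2**K):
            alpha = [(c >> (K - 1 - k)) & 1 for k in range(K)]
            lik = pi[c]
            for j in range(J):
                eta = 1
                for k in range(K):
                    if Q[j, k] == 1 and alpha[k] == 0:
                        eta = 0
                p = 1.0 / (1.0 + np.exp(-(zeta[j] + beta[j] * eta)))
                lik *= p if Y[i, j] == 1 else 1.0 - p
            acc += lik
        total += np.log(acc)
    return total


def dina_em(Y, Q, n_iter=500):
    """Marginal maximum likelihood for the DINA model by EM.

    E-step: posterior class weights under the current (p0, p1, pi).
    M-step: weighted Bernoulli means within the eta=0 / eta=1 groups.
    Returns (zeta, beta, pi) on the logit scale.
    """
    J, K = Q.shape
    C = 2**K
    c = np.arange(C)[:, None]
    patterns = ((c >> np.arange(K - 1, -1, -1)[None, :]) & 1).astype(float)
    eta = (patterns @ Q.T == Q.sum(axis=1)[None, :]).astype(float)  # (C, J)
    N = Y.shape[0]
    p0 = np.full(J, 0.2)
    p1 = np.full(J, 0.8)
    pi = np.full(C, 1.0 / C)
    for _ in range(n_iter):
        logp1 = np.log(np.where(eta == 1, p1, p0))
        logp0 = np.log(np.where(eta == 1, 1 - p1, 1 - p0))
        ll = Y @ logp1.T + (1 - Y) @ logp0.T + np.log(pi)[None, :]
        m = ll.max(axis=1, keepdims=True)
        w = np.exp(ll - m)
        w /= w.sum(axis=1, keepdims=True)
        pi = w.mean(axis=0)
        g1 = w @ eta  # (N, J) posterior P(eta_ij = 1)
        n1 = g1.sum(axis=0)
        s1 = (Y * g1).sum(axis=0)
        n0 = N - n1
        s0 = Y.sum(axis=0) - s1
        p1 = np.clip(s1 / n1, 1e-6, 1 - 1e-6)
        p0 = np.clip(s0 / n0, 1e-6, 1 - 1e-6)
    zeta = np.log(p0 / (1 - p0))
    beta = np.log(p1 / (1 - p1)) - zeta
    return zeta, beta, pi


def toy_posterior_mean_g(y_count, n, prior, grid=100):
    """E[g | data] for the one-item, one-attribute model by 3-d quadrature.

    Model: each examinee masters the attribute with probability pi1; a
    master answers correctly with probability expit(zeta + beta), a
    non-master with g = expit(zeta).  With a single item the likelihood
    depends on the data only through the total correct count, with marginal
    correct-probability q = pi1 expit(zeta+beta) + (1-pi1) expit(zeta).
    Priors exactly as in the samplers: zeta ~ N(mu_zeta, var_zeta),
    beta ~ N(mu_beta, var_beta) I(beta>0), pi ~ Dirichlet(d0, d0) so
    pi1 ~ Beta(d0, d0).
    """
    from scipy.special import expit

    zg = np.linspace(
        prior.mu_zeta - 6 * np.sqrt(prior.var_zeta),
        prior.mu_zeta + 6 * np.sqrt(prior.var_zeta),
        grid,
    )
    bg = np.linspace(1e-3, prior.mu_beta + 6 * np.sqrt(prior.var_beta), grid)
    pg_ = (np.arange(grid) + 0.5) / grid
    z, b, p1 = np.meshgrid(zg, bg, pg_, indexing="ij")
    logprior = (
        -0.5 * (z - prior.mu_zeta) ** 2 / prior.var_zeta
        - 0.5 * (b - prior.mu_beta) ** 2 / prior.var_beta
        + (prior.delta0 - 1) * (np.log(p1) + np.log(1 - p1))
    )
    q = p1 * expit(z + b) + (1 - p1) * expit(z)
    logpost = logprior + y_count * np.log(q) + (n - y_count) * np.log(1 - q)
    w = np.exp(logpost - logpost.max())
    return float((w * expit(z)).sum() / w.sum())
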