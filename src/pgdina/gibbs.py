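"""Polya-Gamma Gibbs sampler (PGGSA) for the reparameterized DINA model.

One sweep cycles through five blocks, each an exact draw from its full
conditional (acceptance probability 1, no tuning parameters):

1. auxiliaries    W_ij ~ PG(1, |zeta_j + beta_j * eta_ij|)
2. intercepts     zeta_j | . ~ Normal(m, V),
                  V = (1/var_zeta + sum_i W_ij)^-1,
                  m = V * (mu_zeta/var_zeta + sum_i (k_ij - W_ij beta_j eta_ij)),
                  with k_ij = Y_ij - 1/2
3. interactions   beta_j | . ~ Normal(m, V) truncated to (0, inf),
                  V = (1/var_beta + sum_i eta_ij W_ij)^-1,
                  m = V * (mu_beta/var_beta + sum_i eta_ij (k_ij - W_ij zeta_j))
4. latent classes alpha_i | . ~ Categorical over the 2^K patterns with
                  log-weights log pi_c + sum_j [k_ij z_jc - W_ij z_jc^2 / 2],
                  z_jc = zeta_j + beta_j eta_cj
5. class probs    pi | . ~ Dirichlet(delta0 + n_1, ..., delta0 + n_C)

The PG augmentation makes the logistic likelihood conditionally Gaussian in
(zeta, beta); the cosh-tilted auxiliary density combines with the Bernoulli
factor so that the class weights in step 4 reduce to the simple quadratic
form above (exp(y z)/(1+e^z) * cosh(z/2) = exp(k z)/2, and the baseline
PG(1,0) density cancels in the normalization).

Latent classes are indexed 0-based in the canonical bit order of
:class:`~pgdina.model_core.LatentClassSpace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit as _logit
from scipy.stats import truncnorm

from .model_core import (
    ClassProbs,
    ItemParams,
    LatentClassSpace,
    QMatrix,
    ResponseMatrix,
    _all_class_loglik,
    ideal_response_table,
)
from .polya_gamma import pg_fill

__all__ = [
    "PriorSpec",
    "PGAuxiliaries",
    "AugmentedState",
    "ChainResult",
    "update_W",
    "update_zeta",
    "update_beta",
    "class_log_weights",
    "update_alpha",
    "update_pi",
    "run_pggsa",
    "pooled_eap",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: zeta ~ N(mu_zeta, var_zeta), beta ~ N(mu_beta, var_beta) I(beta>0),
    pi ~ Dirichlet(delta0, ..., delta0).

    Defaults are the diffuse choices used throughout: variance 1e5 on both
    item parameters and a flat Dirichlet.
    """

    mu_zeta: float = 0.0
    var_zeta: float = 1e5
    mu_beta: float = 0.0
    var_beta: float = 1e5
    delta0: float = 1.0

    def __post_init__(self):
        if self.var_zeta <= 0 or self.var_beta <= 0:
            raise ValueError("prior variances must be positive")
        if self.delta0 <= 0:
            raise ValueError("delta0 must be positive")


@dataclass
class PGAuxiliaries:
    """N x J matrix of Polya-Gamma auxiliary draws (all entries positive)."""

    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if (self.W <= 0).any() or not np.isfinite(self.W).all():
            raise ValueError("PG auxiliaries must be positive and finite")


@dataclass
class AugmentedState:
    """Current state of one chain (item params, auxiliaries, classes, pi)."""

    params: ItemParams
    W: PGAuxiliaries
    class_index: np.ndarray  # (N,) 0-based class labels
    pi: ClassProbs


@dataclass
class ChainResult:
    """Post-burn-in, thinned draws from one chain plus class accumulators.

    ``class_counts[i, c]`` counts stored sweeps on which examinee i sat in
    class c; normalized it is the per-examinee posterior over the latent
    classes, from which MAP patterns and marginal attribute-mastery
    probabilities derive.
    """

    zeta: np.ndarray  # (S, J)
    beta: np.ndarray  # (S, J)
    pi: np.ndarray  # (S, C)
    class_counts: np.ndarray  # (N, C)
    space: LatentClassSpace
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    acceptance: dict | None = None
    class_draws: np.ndarray | None = None  # (S, N) optional

    @property
    def n_stored(self) -> int:
        return self.zeta.shape[0]

    def eap_zeta(self) -> np.ndarray:
        return self.zeta.mean(axis=0)

    def eap_beta(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def eap_pi(self) -> np.ndarray:
        return self.pi.mean(axis=0)

    def class_posterior(self) -> np.ndarray:
        """(N, C) per-examinee posterior class frequencies."""
        tot = self.class_counts.sum(axis=1, keepdims=True)
        return self.class_counts / tot

    def attribute_marginals(self) -> np.ndarray:
        """(N, K) marginal posterior mastery probabilities."""
        return self.class_posterior() @ self.space.patterns

    def map_class(self) -> np.ndarray:
        """(N,) modal latent class (ties broken to the lowest index)."""
        return self.class_counts.argmax(axis=1)


# ---------------------------------------------------------------------------
# single-block updates (the unit-testable surface; the runner vectorizes them)


def update_W(state: AugmentedState, eta_table: np.ndarray, rng: np.random.Generator) -> PGAuxiliaries:
    """Step 1: fresh W_ij ~ PG(1, |zeta_j + beta_j * eta_{c(i), j}|)."""
    eta_i = eta_table[state.class_index]  # (N, J)
    z = state.params.zeta[None, :] + state.params.beta[None, :] * eta_i
    W = np.empty_like(z)
    pg_fill(z, W, rng)
    return PGAuxiliaries(W)


def update_zeta(j, Y, W, eta_col, params: ItemParams, prior: PriorSpec, rng) -> float:
    """Step 2 for one item: Gaussian full-conditional draw of zeta_j."""
    y = np.asarray(Y, dtype=float)[:, j] if np.ndim(Y) == 2 else np.asarray(Y, dtype=float)
    w = np.asarray(W, dtype=float)[:, j] if np.ndim(W) == 2 else np.asarray(W, dtype=float)
    eta = np.asarray(eta_col, dtype=float)
    k = y - 0.5
    V = 1.0 / (1.0 / prior.var_zeta + w.sum())
    m = V * (prior.mu_zeta / prior.var_zeta + (k - w * params.beta[j] * eta).sum())
    return float(m + np.sqrt(V) * rng.standard_normal())


def update_beta(j, Y, W, eta_col, params: ItemParams, prior: PriorSpec, rng) -> float:
    """Step 3 for one item: truncated-normal (0, inf) draw of beta_j."""
    y = np.asarray(Y, dtype=float)[:, j] if np.ndim(Y) == 2 else np.asarray(Y, dtype=float)
    w = np.asarray(W, dtype=float)[:, j] if np.ndim(W) == 2 else np.asarray(W, dtype=float)
    eta = np.asarray(eta_col, dtype=float)
    k = y - 0.5
    V = 1.0 / (1.0 / prior.var_beta + (eta * w).sum())  # eta^2 = eta (binary)
    m = V * (prior.mu_beta / prior.var_beta + (eta * (k - w * params.zeta[j])).sum())
    sd = np.sqrt(V)
    return float(truncnorm.rvs(-m / sd, np.inf, loc=m, scale=sd, random_state=rng))


def class_log_weights(Y_i, W_i, params: ItemParams, eta_table, pi: ClassProbs) -> np.ndarray:
    """Step 4 weights (up to a constant): log pi_c + sum_j [k_ij z_jc - W_ij z_jc^2 / 2]."""
    y = np.asarray(Y_i, dtype=float)
    w = np.asarray(W_i, dtype=float)
    k = y - 0.5
    Z = params.zeta[None, :] + params.beta[None, :] * np.asarray(eta_table, dtype=float)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi.pi)
    return logpi + Z @ k - 0.5 * (Z**2) @ w


def update_alpha(i, weights, rng: np.random.Generator) -> int:
    """Categorical draw with probabilities softmax(weights)."""
    w = np.asarray(weights, dtype=float)
    m = w.max()
    if not np.isfinite(m):
        raise ValueError("all class weights are -inf; degenerate state")
    p = np.exp(w - m)
    p /= p.sum()
    return int(rng.choice(p.size, p=p))


def update_pi(class_index, delta0: float, C: int, rng: np.random.Generator) -> ClassProbs:
    """Step 5: Dirichlet(delta0 + n_1, ..., delta0 + n_C) draw."""
    counts = np.bincount(np.asarray(class_index, dtype=int), minlength=C)
    return ClassProbs(rng.dirichlet(delta0 + counts))


# ---------------------------------------------------------------------------
# full sampler


def _categorical_rows(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of an (N, C) log-weight matrix."""
    m = logw.max(axis=1, keepdims=True)
    p = np.exp(logw - m)
    cum = np.cumsum(p, axis=1)
    u = rng.random(logw.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


def _initial_state(Y, eta_table, C, rng, overdisperse):
    N, J = Y.shape
    pbar = np.clip(Y.mean(axis=0), 0.05, 0.95)
    zeta = np.asarray(_logit(pbar), dtype=float)
    beta = np.ones(J)
    if overdisperse:
        zeta = zeta + rng.standard_normal(J)
        beta = np.maximum(0.05, beta + rng.standard_normal(J))
    class_index = rng.integers(0, C, size=N)
    pi = np.full(C, 1.0 / C)
    return zeta, beta, class_index, pi


def run_pggsa(
    Y: ResponseMatrix,
    Q: QMatrix,
    prior: PriorSpec = PriorSpec(),
    n_iter: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    n_chains: int = 1,
    seed: int = 0,
    init: dict | None = None,
    collapsed: bool = False,
    store_class_draws: bool = False,
) -> list[ChainResult]:
    """Run the five-step PG Gibbs sampler; returns one ChainResult per chain.

    Chain c uses ``numpy.random.default_rng(seed + c)``; runs are bit
    reproducible for a given seed.  ``collapsed=True`` drops the W factor
    from the step-4 class weights (plain Bernoulli-likelihood weights); the
    default keeps the exact conditional.  ``init`` may override any of
    ``zeta``, ``beta``, ``class_index``, ``pi``.
    """
    if Y.J != Q.J:
        raise ValueError(f"Y has {Y.J} items but Q has {Q.J}")
    if not (0 <= burn_in < n_iter):
        raise ValueError("need 0 <= burn_in < n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    space = LatentClassSpace(Q.K)
    C = space.C
    eta_tab = ideal_response_table(Q, space).astype(float)  # (C, J)
    Ymat = Y.entries.astype(float)
    N, J = Ymat.shape
    kmat = Ymat - 0.5
    ksum_j = kmat.sum(axis=0)

    results = []
    for chain in range(n_chains):
        rng = np.random.default_rng(seed + chain)
        zeta, beta, class_index, pi = _initial_state(
            Ymat, eta_tab, C, rng, overdisperse=n_chains > 1
        )
        if init:
            zeta = np.asarray(init.get("zeta", zeta), dtype=float).copy()
            beta = np.asarray(init.get("beta", beta), dtype=float).copy()
            class_index = np.asarray(init.get("class_index", class_index), dtype=int).copy()
            pi = np.asarray(init.get("pi", pi), dtype=float).copy()

        n_store = (n_iter - burn_in + thin - 1) // thin
        zeta_draws = np.empty((n_store, J))
        beta_draws = np.empty((n_store, J))
        pi_draws = np.empty((n_store, C))
        class_counts = np.zeros((N, C), dtype=np.int64)
        cls_draws = np.empty((n_store, N), dtype=np.int32) if store_class_draws else None

        W = np.empty((N, J))
        s = 0
        for it in range(n_iter):
            eta_i = eta_tab[class_index]  # (N, J)

            # Step 1: PG auxiliaries at the current linear predictor
            z = zeta[None, :] + beta[None, :] * eta_i
            pg_fill(z, W, rng)

            # Step 2: all intercepts (conditionally independent across items)
            Vz = 1.0 / (1.0 / prior.var_zeta + W.sum(axis=0))
            mz = Vz * (prior.mu_zeta / prior.var_zeta + ksum_j - (W * eta_i).sum(axis=0) * beta)
            zeta = mz + np.sqrt(Vz) * rng.standard_normal(J)

            # Step 3: all interactions, truncated to (0, inf)
            ew = W * eta_i
            Vb = 1.0 / (1.0 / prior.var_beta + ew.sum(axis=0))
            mb = Vb * (prior.mu_beta / prior.var_beta + (eta_i * kmat).sum(axis=0) - ew.sum(axis=0) * zeta)
            sdb = np.sqrt(Vb)
            beta = np.atleast_1d(
                truncnorm.rvs(-mb / sdb, np.inf, loc=mb, scale=sdb, random_state=rng)
            )

            # Step 4: latent classes
            with np.errstate(divide="ignore"):
                logpi = np.log(pi)
            Z = zeta[None, :] + beta[None, :] * eta_tab  # (C, J)
            if collapsed:
                logw = _all_class_loglik(Ymat, ItemParams(zeta, beta), eta_tab) + logpi[None, :]
            else:
                logw = kmat @ Z.T - 0.5 * (W @ (Z**2).T) + logpi[None, :]
            class_index = _categorical_rows(logw, rng)

            # Step 5: class probabilities
            counts = np.bincount(class_index, minlength=C)
            pi = rng.dirichlet(prior.delta0 + counts)

            if it >= burn_in and (it - burn_in) % thin == 0:
                zeta_draws[s] = zeta
                beta_draws[s] = beta
                pi_draws[s] = pi
                class_counts[np.arange(N), class_index] += 1
                if cls_draws is not None:
                    cls_draws[s] = class_index
                s += 1

        results.append(
            ChainResult(
                zeta=zeta_draws,
                beta=beta_draws,
                pi=pi_draws,
                class_counts=class_counts,
                space=space,
                n_iter=n_iter,
                burn_in=burn_in,
                thin=thin,
                seed=seed + chain,
                class_draws=cls_draws,
            )
        )
    return results


def pooled_eap(chains: list[ChainResult]) -> dict[str, np.ndarray]:
    """Pool draws across chains and return EAP estimates for zeta, beta, pi."""
    zeta = np.concatenate([c.zeta for c in chains]).mean(axis=0)
    beta = np.concatenate([c.beta for c in chains]).mean(axis=0)
    pi = np.concatenate([c.pi for c in chains]).mean(axis=0)
    counts = sum(c.class_counts for c in chains)
    post = counts / counts.sum(axis=1, keepdims=True)
    return {"zeta": zeta, "beta": beta, "pi": pi, "class_posterior": post}
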