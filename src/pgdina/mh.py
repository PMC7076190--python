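"""Random-walk Metropolis-Hastings baseline sampler for the DINA item parameters.

The comparison baseline updates zeta_j and beta_j sequentially per item with
Gaussian random-walk proposals (the beta proposal truncated at 0, with the
usual Phi-ratio correction in the acceptance probability), while the latent
classes and pi are updated by the same Gibbs blocks as the PG sampler but
with plain Bernoulli-likelihood class weights (no auxiliary W enters the MH
scheme).  Proposal scales are fixed, not adapted: the point of the baseline
is precisely that its efficiency hinges on manual tuning.

Because eta_ij is binary, the item-j log-likelihood depends on the data only
through four sufficient statistics (counts and correct-counts within the
eta=1 and eta=0 groups), which keeps the per-item update O(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, truncnorm

from .model_core import (
    ItemParams,
    LatentClassSpace,
    QMatrix,
    ResponseMatrix,
    _all_class_loglik,
    ideal_response_table,
)
from .gibbs import ChainResult, PriorSpec, _categorical_rows, _initial_state

__all__ = ["MHProposalSpec", "mh_update_item", "run_mh"]


@dataclass(frozen=True)
class MHProposalSpec:
    """Random-walk proposal standard deviations for zeta and beta.

    The two reference tunings are stated as proposal *variances* 0.1 and 1;
    use :meth:`from_variances` for those.
    """

    sd_zeta: float
    sd_beta: float

    def __post_init__(self):
        if self.sd_zeta <= 0 or self.sd_beta <= 0:
            raise ValueError("proposal standard deviations must be positive")

    @classmethod
    def from_variances(cls, var_zeta: float, var_beta: float) -> "MHProposalSpec":
        return cls(float(np.sqrt(var_zeta)), float(np.sqrt(var_beta)))


def _item_loglik(zeta, beta, n1, s1, n0, s0):
    """Item log-likelihood from group sufficient statistics (vectorizable)."""
    z1 = zeta + beta
    return (
        s1 * z1 - n1 * np.logaddexp(0.0, z1) + s0 * zeta - n0 * np.logaddexp(0.0, zeta)
    )


def mh_update_item(
    j: int,
    Y,
    eta_col,
    params: ItemParams,
    prior: PriorSpec,
    prop: MHProposalSpec,
    rng: np.random.Generator,
) -> tuple[float, float, tuple[bool, bool]]:
    """One MH update of (zeta_j, beta_j): zeta first, then beta, each with its
    own accept/reject.  Returns the new values and the two accepted flags."""
    y = np.asarray(Y, dtype=float)[:, j] if np.ndim(Y) == 2 else np.asarray(Y, dtype=float)
    eta = np.asarray(eta_col, dtype=float)
    n1 = eta.sum()
    s1 = (y * eta).sum()
    n0 = y.size - n1
    s0 = y.sum() - s1
    zeta, beta = float(params.zeta[j]), float(params.beta[j])

    # intercept: symmetric normal random walk
    zeta_prop = zeta + prop.sd_zeta * rng.standard_normal()
    logr = (
        _item_loglik(zeta_prop, beta, n1, s1, n0, s0)
        - _item_loglik(zeta, beta, n1, s1, n0, s0)
        - 0.5 * ((zeta_prop - prior.mu_zeta) ** 2 - (zeta - prior.mu_zeta) ** 2) / prior.var_zeta
    )
    acc_z = np.log(rng.random()) < logr
    if acc_z:
        zeta = zeta_prop

    # interaction: normal random walk truncated at 0; the proposal
    # normalizers contribute Phi(beta/sd) / Phi(beta'/sd) to the ratio
    a = -beta / prop.sd_beta
    beta_prop = float(truncnorm.rvs(a, np.inf, loc=beta, scale=prop.sd_beta, random_state=rng))
    logr = (
        _item_loglik(zeta, beta_prop, n1, s1, n0, s0)
        - _item_loglik(zeta, beta, n1, s1, n0, s0)
        - 0.5 * ((beta_prop - prior.mu_beta) ** 2 - (beta - prior.mu_beta) ** 2) / prior.var_beta
        + norm.logcdf(beta / prop.sd_beta)
        - norm.logcdf(beta_prop / prop.sd_beta)
    )
    acc_b = np.log(rng.random()) < logr
    if acc_b:
        beta = beta_prop
    return zeta, beta, (bool(acc_z), bool(acc_b))


def run_mh(
    Y: ResponseMatrix,
    Q: QMatrix,
    prior: PriorSpec = PriorSpec(),
    prop: MHProposalSpec = MHProposalSpec.from_variances(0.1, 0.1),
    n_iter: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    n_chains: int = 1,
    seed: int = 0,
    init: dict | None = None,
) -> list[ChainResult]:
    """MH baseline: item-wise random-walk updates, then Gibbs alpha and pi.

    Returns one :class:`~pgdina.gibbs.ChainResult` per chain; per-parameter
    acceptance rates (over all iterations) are in ``result.acceptance``.
    """
    if Y.J != Q.J:
        raise ValueError(f"Y has {Y.J} items but Q has {Q.J}")
    if not (0 <= burn_in < n_iter):
        raise ValueError("need 0 <= burn_in < n_iter")
    space = LatentClassSpace(Q.K)
    C = space.C
    eta_tab = ideal_response_table(Q, space).astype(float)
    Ymat = Y.entries.astype(float)
    N, J = Ymat.shape
    ysum = Ymat.sum(axis=0)

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
        acc_z = np.zeros(J)
        acc_b = np.zeros(J)

        s = 0
        for it in range(n_iter):
            eta_i = eta_tab[class_index]
            n1 = eta_i.sum(axis=0)
            s1 = (Ymat * eta_i).sum(axis=0)
            n0 = N - n1
            s0 = ysum - s1

            # zeta block (vectorized across items; independent proposals)
            zeta_prop = zeta + prop.sd_zeta * rng.standard_normal(J)
            logr = (
                _item_loglik(zeta_prop, beta, n1, s1, n0, s0)
                - _item_loglik(zeta, beta, n1, s1, n0, s0)
                - 0.5 * ((zeta_prop - prior.mu_zeta) ** 2 - (zeta - prior.mu_zeta) ** 2) / prior.var_zeta
            )
            keep = np.log(rng.random(J)) < logr
            zeta = np.where(keep, zeta_prop, zeta)
            acc_z += keep

            # beta block (truncated proposals)
            beta_prop = np.atleast_1d(truncnorm.rvs(
                -beta / prop.sd_beta, np.inf, loc=beta, scale=prop.sd_beta, random_state=rng
            ))
            logr = (
                _item_loglik(zeta, beta_prop, n1, s1, n0, s0)
                - _item_loglik(zeta, beta, n1, s1, n0, s0)
                - 0.5 * ((beta_prop - prior.mu_beta) ** 2 - (beta - prior.mu_beta) ** 2) / prior.var_beta
                + norm.logcdf(beta / prop.sd_beta)
                - norm.logcdf(beta_prop / prop.sd_beta)
            )
            keep = np.log(rng.random(J)) < logr
            beta = np.where(keep, beta_prop, beta)
            acc_b += keep

            # latent classes with plain Bernoulli weights, then pi
            with np.errstate(divide="ignore"):
                logpi = np.log(pi)
            logw = _all_class_loglik(Ymat, ItemParams(zeta, beta), eta_tab) + logpi[None, :]
            class_index = _categorical_rows(logw, rng)
            counts = np.bincount(class_index, minlength=C)
            pi = rng.dirichlet(prior.delta0 + counts)

            if it >= burn_in and (it - burn_in) % thin == 0:
                zeta_draws[s] = zeta
                beta_draws[s] = beta
                pi_draws[s] = pi
                class_counts[np.arange(N), class_index] += 1
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
                acceptance={"zeta": acc_z / n_iter, "beta": acc_b / n_iter},
            )
        )
    return results
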