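"""Synthetic data generation and the recovery/classification study designs.

The generator draws each examinee's latent class from pi (flat over the 2^K
patterns by default), forms the ideal responses against a Q-matrix, and
draws Y_ij ~ Bernoulli(g_j + (1 - s_j - g_j) eta_ij).  The four named noise
levels fix (s_j, g_j) for every item:

    LNL (low noise)             s = g = 0.1
    HNL (high noise)            s = g = 0.2
    SHG (slipping > guessing)   s = 0.2, g = 0.1
    GHS (guessing > slipping)   s = 0.1, g = 0.2

The reference 30-item, 5-attribute Q-matrix (:func:`study_q_matrix`) puts
two unit rows per attribute, all ten two-attribute items, and nine of the
three-attribute items plus one duplicated two-attribute row; it satisfies
the Gu-Xu identifiability conditions.

Recovery is scored by Bias and MSE of the EAP estimates across replicate
datasets, and classification by CPCR (exact pattern match rate) and AAMA
(per-attribute match rate).  Four pre-configured studies are provided:

1. parameter recovery across noise levels and sample sizes (PG sampler);
2. PG sampler vs the random-walk MH baseline at two proposal tunings;
3. sensitivity to four prior types (informative to diffuse);
4. attribute classification accuracy across noise levels.

Each study runs at ``full`` scale (25 replications, 20,000 iterations with
10,000 burn-in — hours of compute) or ``reduced`` scale (5 replications,
4,000 iterations with 2,000 burn-in, single chain) with identical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import ChainResult, PriorSpec, pooled_eap, run_pggsa
from .mh import MHProposalSpec, run_mh
from .model_core import (
    ClassProbs,
    ItemParams,
    LatentClassSpace,
    QMatrix,
    ResponseMatrix,
    ideal_response_table,
    reparameterize,
)

__all__ = [
    "NOISE_LEVELS",
    "study_q_matrix",
    "SimulationCondition",
    "generate_dataset",
    "bias",
    "mse",
    "classification_metrics",
    "attribute_point_estimates",
    "run_study",
]

#: named (slipping, guessing) noise levels
NOISE_LEVELS = {
    "LNL": (0.1, 0.1),
    "HNL": (0.2, 0.2),
    "SHG": (0.2, 0.1),
    "GHS": (0.1, 0.2),
}

# 30 items x 5 attributes; row 30 duplicates row 20 as designed.
_STUDY_Q_ROWS = [
    "10000", "01000", "00100", "00010", "00001",
    "10000", "01000", "00100", "00010", "00001",
    "11000", "10100", "10010", "10001", "01100",
    "01010", "01001", "00110", "00101", "00011",
    "11100", "11010", "11001", "10110", "10101",
    "10011", "01110", "01101", "01011", "00011",
]


def study_q_matrix() -> QMatrix:
    """The reference 30-item, 5-attribute simulation Q-matrix."""
    rows = [[int(ch) for ch in r] for r in _STUDY_Q_ROWS]
    return QMatrix(np.array(rows, dtype=np.int8))


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of a simulation design.

    ``noise`` is a named level (key of :data:`NOISE_LEVELS`) or an explicit
    ``(s, g)`` pair of scalars/arrays; ``true_pi`` defaults to flat over the
    2^K classes.
    """

    N: int
    Q: QMatrix
    noise: str | tuple = "LNL"
    true_pi: ClassProbs | None = None
    seed: int = 0
    replications: int = 1

    def sg(self) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(self.noise, str):
            try:
                s, g = NOISE_LEVELS[self.noise]
            except KeyError:
                raise ValueError(f"unknown noise level {self.noise!r}") from None
        else:
            s, g = self.noise
        J = self.Q.J
        return np.broadcast_to(np.asarray(s, float), (J,)).copy(), np.broadcast_to(
            np.asarray(g, float), (J,)
        ).copy()

    def pi(self) -> ClassProbs:
        return self.true_pi or ClassProbs.uniform(2**self.Q.K)


def generate_dataset(cond: SimulationCondition, rng: np.random.Generator):
    """Simulate (Y, truth) under a condition.

    Returns the response matrix and a truth dict with the drawn class
    indices, attribute patterns, pi, (s, g) and — when both lie strictly in
    (0, 1) — the implied ItemParams.  Degenerate s = g = 0 is allowed (Y
    then equals the ideal-response table deterministically).
    """
    s, g = cond.sg()
    pi = cond.pi()
    space = LatentClassSpace(cond.Q.K)
    eta_tab = ideal_response_table(cond.Q, space)
    class_index = rng.choice(space.C, size=cond.N, p=pi.pi)
    eta = eta_tab[class_index]  # (N, J)
    p = np.where(eta == 1, 1.0 - s[None, :], g[None, :])
    Y = (rng.random((cond.N, cond.Q.J)) < p).astype(np.int8)
    truth = {
        "class_index": class_index,
        "alpha": space.patterns[class_index],
        "pi": pi,
        "s": s,
        "g": g,
        "params": None,
    }
    if ((s > 0) & (s < 1) & (g > 0) & (g < 1)).all():
        zeta, beta = reparameterize(s, g)
        truth["params"] = ItemParams(zeta, beta)
    return ResponseMatrix(Y), truth


def bias(estimates, truth: float) -> float:
    """(1/M) sum_m (estimate_m - truth)."""
    e = np.asarray(estimates, dtype=float)
    return float((e - truth).mean())


def mse(estimates, truth: float) -> float:
    """(1/M) sum_m (estimate_m - truth)^2."""
    e = np.asarray(estimates, dtype=float)
    return float(((e - truth) ** 2).mean())


def classification_metrics(alpha_hat, alpha_true) -> tuple[float, float]:
    """(CPCR, AAMA): exact-pattern and per-attribute match rates."""
    ah = np.asarray(alpha_hat)
    at = np.asarray(alpha_true)
    if ah.shape != at.shape:
        raise ValueError(f"shape mismatch: {ah.shape} vs {at.shape}")
    match = ah == at
    return float(match.all(axis=1).mean()), float(match.mean())


def attribute_point_estimates(chain, rule: str = "map") -> np.ndarray:
    """N x K binary attribute estimates from one ChainResult or a list of chains.

    ``rule='map'``: modal latent class per examinee (posterior class
    frequencies pooled across chains), then its pattern.  ``rule='threshold'``:
    marginal mastery probabilities thresholded at 0.5.
    """
    chains = chain if isinstance(chain, (list, tuple)) else [chain]
    if not chains or chains[0].n_stored == 0:
        raise ValueError("no stored draws")
    space = chains[0].space
    counts = sum(c.class_counts for c in chains)
    if rule == "map":
        return space.patterns[counts.argmax(axis=1)]
    if rule == "threshold":
        post = counts / counts.sum(axis=1, keepdims=True)
        return (post @ space.patterns >= 0.5).astype(np.int8)
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# study runners

_SCALES = {
    "full": {"replications": 25, "n_iter": 20000, "burn_in": 10000, "n_chains": 4},
    "reduced": {"replications": 5, "n_iter": 4000, "burn_in": 2000, "n_chains": 1},
}

_STUDY3_PRIOR_VARS = {"I": 0.5, "II": 1.0, "III": 1e3, "IV": 1e5}


def _noise_prior(noise: str, var: float = 1e5) -> PriorSpec:
    """Diffuse prior centered at the true reparameterized values of a noise level."""
    s, g = NOISE_LEVELS[noise]
    zeta, beta = reparameterize(s, g)
    return PriorSpec(mu_zeta=zeta, var_zeta=var, mu_beta=beta, var_beta=var, delta0=1.0)


def _rep_metrics(Y, truth, Q, sampler, prior, mcmc, fit_seed, prop=None):
    """Fit one replicate and return its EAPs, classification and acceptance."""
    if sampler == "pggsa":
        chains = run_pggsa(Y, Q, prior=prior, seed=fit_seed, **mcmc)
    elif sampler == "mh":
        chains = run_mh(Y, Q, prior=prior, prop=prop, seed=fit_seed, **mcmc)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    est = pooled_eap(chains)
    alpha_hat = attribute_point_estimates(chains, rule="map")
    cpcr, aama = classification_metrics(alpha_hat, truth["alpha"])
    acc = chains[0].acceptance
    return est, cpcr, aama, acc


def _aggregate(rows, truth_params, truth_pi):
    """Average Eq.-style Bias/MSE across items (zeta, beta) and classes (pi)."""
    zeta_hat = np.stack([r[0]["zeta"] for r in rows])  # (M, J)
    beta_hat = np.stack([r[0]["beta"] for r in rows])
    pi_hat = np.stack([r[0]["pi"] for r in rows])  # (M, C)
    zt, bt = truth_params.zeta, truth_params.beta
    out = {
        "bias_zeta": float((zeta_hat - zt).mean()),
        "mse_zeta": float(((zeta_hat - zt) ** 2).mean(axis=0).mean()),
        "bias_beta": float((beta_hat - bt).mean()),
        "mse_beta": float(((beta_hat - bt) ** 2).mean(axis=0).mean()),
        "bias_pi": float((pi_hat - truth_pi.pi).mean()),
        "mse_pi": float(((pi_hat - truth_pi.pi) ** 2).mean(axis=0).mean()),
        "cpcr": float(np.mean([r[1] for r in rows])),
        "aama": float(np.mean([r[2] for r in rows])),
    }
    return out


def _resolve_scale(scale, overrides):
    cfg = dict(_SCALES[scale])
    for key, val in overrides.items():
        if val is not None:
            cfg[key] = val
    mcmc = {k: cfg[k] for k in ("n_iter", "burn_in", "n_chains")}
    return cfg["replications"], mcmc


def run_study(
    study: int,
    scale: str = "reduced",
    seed: int = 0,
    noise_levels=None,
    sample_sizes=None,
    replications: int | None = None,
    n_iter: int | None = None,
    burn_in: int | None = None,
    n_chains: int | None = None,
) -> pd.DataFrame:
    """Run one of the four pre-configured simulation studies.

    Replicate r of a condition simulates data with seed ``seed*1000 + r`` and
    fits with seed ``seed*1000 + 500 + r``, so every number is reproducible
    from the single top-level seed.  Returns a tidy DataFrame with one row
    per condition (x algorithm / prior type where applicable).
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}")
    reps, mcmc = _resolve_scale(
        scale, {"replications": replications, "n_iter": n_iter, "burn_in": burn_in, "n_chains": n_chains}
    )
    Q = study_q_matrix()
    noise_levels = list(noise_levels or NOISE_LEVELS)

    def make_data(noise, N, r):
        cond = SimulationCondition(N=N, Q=Q, noise=noise)
        return generate_dataset(cond, np.random.default_rng(seed * 1000 + r))

    records = []
    if study == 1:
        sample_sizes = list(sample_sizes or ([1000, 2000] if scale == "full" else [1000]))
        for noise in noise_levels:
            prior = _noise_prior(noise)
            for N in sample_sizes:
                rows = []
                for r in range(reps):
                    Y, truth = make_data(noise, N, r)
                    rows.append(
                        _rep_metrics(Y, truth, Q, "pggsa", prior, mcmc, seed * 1000 + 500 + r)
                    )
                _, truth = make_data(noise, N, 0)
                rec = {"study": 1, "noise": noise, "N": N}
                rec.update(_aggregate(rows, truth["params"], truth["pi"]))
                records.append(rec)
    elif study == 2:
        N = (sample_sizes or [1000])[0]
        noise = (noise_levels or ["LNL"])[0] if noise_levels else "LNL"
        prior = _noise_prior(noise)
        algos = [
            ("pggsa", None, "PGGSA"),
            ("mh", MHProposalSpec.from_variances(0.1, 0.1), "MH case 1 (var 0.1)"),
            ("mh", MHProposalSpec.from_variances(1.0, 1.0), "MH case 2 (var 1)"),
        ]
        datasets = [make_data(noise, N, r) for r in range(reps)]
        for sampler, prop, label in algos:
            rows = [
                _rep_metrics(Y, truth, Q, sampler, prior, mcmc, seed * 1000 + 500 + r, prop=prop)
                for r, (Y, truth) in enumerate(datasets)
            ]
            rec = {"study": 2, "noise": noise, "N": N, "algorithm": label}
            rec.update(_aggregate(rows, datasets[0][1]["params"], datasets[0][1]["pi"]))
            acc = rows[0][3]
            if acc is not None:
                rec["acc_zeta"] = float(np.mean(acc["zeta"]))
                rec["acc_beta"] = float(np.mean(acc["beta"]))
            records.append(rec)
    elif study == 3:
        N = (sample_sizes or [1000])[0]
        noise = "LNL"
        s, g = NOISE_LEVELS[noise]
        zt, bt = reparameterize(s, g)
        # common random numbers: the same replicate datasets under every prior type
        datasets = [make_data(noise, N, r) for r in range(reps)]
        for ptype, var in _STUDY3_PRIOR_VARS.items():
            prior = PriorSpec(mu_zeta=zt, var_zeta=var, mu_beta=bt, var_beta=var, delta0=1.0)
            rows = [
                _rep_metrics(Y, truth, Q, "pggsa", prior, mcmc, seed * 1000 + 500 + r)
                for r, (Y, truth) in enumerate(datasets)
            ]
            rec = {"study": 3, "noise": noise, "N": N, "prior_type": ptype, "prior_var": var}
            rec.update(_aggregate(rows, datasets[0][1]["params"], datasets[0][1]["pi"]))
            records.append(rec)
    elif study == 4:
        N = (sample_sizes or [1000])[0]
        if replications is None and scale == "reduced":
            reps = 1  # classification rates are already N-examinee averages
        for noise in noise_levels:
            prior = _noise_prior(noise)
            rows = []
            for r in range(reps):
                Y, truth = make_data(noise, N, r)
                rows.append(_rep_metrics(Y, truth, Q, "pggsa", prior, mcmc, seed * 1000 + 500 + r))
            _, truth = make_data(noise, N, 0)
            rec = {"study": 4, "noise": noise, "N": N}
            rec.update(_aggregate(rows, truth["params"], truth["pi"]))
            records.append(rec)
    else:
        raise ValueError("study must be 1, 2, 3 or 4")

    return pd.DataFrame.from_records(records)
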