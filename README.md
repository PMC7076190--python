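# pgdina

Fully Bayesian estimation of the **DINA** cognitive diagnosis model with a
**Pólya-Gamma Gibbs sampler**.

Cognitive diagnosis models classify examinees on a set of fine-grained binary
skills ("attributes") from their right/wrong answers on a test. In the DINA
("deterministic inputs, noisy AND gate") model, examinee *i* holds a binary
mastery pattern **α**ᵢ ∈ {0,1}ᴷ, item *j* requires the attributes flagged in
row *j* of a binary Q-matrix, and the ideal response is the conjunction

&nbsp;&nbsp;&nbsp;&nbsp;η*ᵢⱼ* = ∏ₖ α*ᵢₖ*^q*ⱼₖ*.

A correct answer occurs with probability 1 − *s*ⱼ when η = 1 (slipping *s*ⱼ)
and *g*ⱼ when η = 0 (guessing *g*ⱼ). On the logit scale this is a two-level
logistic model,

&nbsp;&nbsp;&nbsp;&nbsp;logit P(Y*ᵢⱼ* = 1) = ζⱼ + βⱼ η*ᵢⱼ*,&nbsp;&nbsp;
ζⱼ = logit *g*ⱼ,&nbsp; βⱼ = logit(1 − *s*ⱼ) − logit *g*ⱼ > 0,

with latent class probabilities **π** over the C = 2ᴷ patterns. Augmenting
each response with a Pólya-Gamma variable W*ᵢⱼ* ~ PG(1, |ζⱼ + βⱼη*ᵢⱼ*|) makes
every full conditional a standard distribution — Gaussian for ζⱼ, truncated
Gaussian for βⱼ, categorical for the latent classes, Dirichlet for **π** — so
the whole model is estimated by an exact Gibbs sampler with acceptance
probability 1 and **no tuning parameters**, unlike random-walk
Metropolis-Hastings (also included, as a baseline).

The package provides:

- `model_core` types (`QMatrix`, `ResponseMatrix`, `ItemParams`, …), the
  ζ/β ↔ s/g transforms, and the latent-class likelihood;
- an exact Devroye-type PG(1, z) generator (numba-compiled, ~10⁷ draws/s);
- `run_pggsa` — the five-block PG Gibbs sampler; `run_mh` — the MH baseline;
- Gu–Xu Q-matrix identifiability checks (`check_identifiability`);
- Brooks–Gelman PSRF diagnostics and EAP/SD/HPDI posterior summaries;
- a simulation engine (`generate_dataset`, `run_study`) reproducing the
  four standard recovery/classification study designs;
- a `pgdina` CLI with `fit`, `diagnose`, `simulate`, `study`, `check-q`.

Intended users: psychometricians and methodologists fitting conjunctive
cognitive diagnosis models to binary assessment data, or benchmarking MCMC
schemes for them.

## Worked example

```python
import numpy as np
import pgdina as pg

Q = pg.study_q_matrix()                      # 30 items x 5 attributes
print(pg.check_identifiability(Q).identifiable)   # True

cond = pg.SimulationCondition(N=1000, Q=Q, noise="LNL")   # s = g = 0.1
Y, truth = pg.generate_dataset(cond, np.random.default_rng(1))

chains = pg.run_pggsa(Y, Q, n_iter=4000, burn_in=2000, seed=1)
est = pg.pooled_eap(chains)
print(np.round(est["zeta"][:3], 3), np.round(est["beta"][:3], 3))

alpha_hat = pg.attribute_point_estimates(chains)
print(pg.classification_metrics(alpha_hat, truth["alpha"]))
```

Output:

```
True
[-1.92  -1.967 -2.298] [4.203 4.357 4.83 ]
(0.906, 0.9776)
```

The first line confirms the Q-matrix passes the Gu–Xu conditions. The EAPs
of the first three intercepts/interactions sit near their true values
(ζ = −2.1972, β = 4.3945 under low noise, i.e. s = g = 0.1). The last line
is (CPCR, AAMA): 90.6% of the 1,000 examinees have their entire 5-attribute
pattern recovered exactly, and 97.8% of the 5,000 individual attribute
judgements are correct — at the Bayes-oracle level for this noise setting.

The same fit from the shell:

```sh
pgdina simulate --n 1000 --noise LNL --seed 1 --out sim/
pgdina fit --y sim/Y.csv --q sim/Q.csv --chains 4 --iterations 4000 \
           --burn-in 2000 --seed 1 --out run/
pgdina diagnose --run-dir run/        # PSRF table, flags values >= 1.1
pgdina check-q sim/Q.csv
```

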