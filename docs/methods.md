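# Methods

## Model

The DINA model for N examinees, J items and K binary attributes:

- Latent class: examinee *i* carries a mastery pattern **α**ᵢ ∈ {0,1}ᴷ,
  one of C = 2ᴷ classes drawn with probabilities **π** (a point on the
  C-simplex). Classes are indexed canonically by the integer value of the
  bit string with the first attribute as the most significant bit, so class
  0 is "masters nothing" and class C−1 "masters everything". This ordering
  is a package convention (needed for π indexing and serialization); any
  fixed ordering would do.
- Ideal response: η_ij = ∏ₖ α_ik^q_jk with Q = {q_jk} the J×K binary
  Q-matrix. Items requiring no attribute are rejected at load time: for such
  an item η ≡ 1 and the two item parameters are confounded.
- Response model, logit scale: logit P(Y_ij = 1) = ζⱼ + βⱼ η_ij, with
  ζⱼ = logit gⱼ and βⱼ = logit(1−sⱼ) − logit gⱼ. The constraint βⱼ > 0 is
  the usual monotonicity/identification restriction (1 − sⱼ > gⱼ, positive
  item discrimination index). Probabilities are clipped to
  [1e−12, 1−1e−12] before any logit so file-loaded boundary values cannot
  produce infinities.
- Marginal likelihood: ∑ᵢ log ∑_c π_c p(Yᵢ | class c), computed in the log
  domain with log-sum-exp (N·J products of probabilities underflow even at
  modest sizes).

Identifiability of all parameters holds iff (Gu–Xu): Q contains the K×K
identity up to row permutation; every attribute is required by ≥ 3 items;
and the columns of the remaining submatrix are pairwise distinct.
`check_identifiability` reports all three. A failing Q-matrix produces a
warning, not an error — real assessments (e.g. the classic 15-item fraction
subtraction test, whose Q-matrix is not complete) are routinely analyzed
regardless, and the posterior remains well-defined.

## The Pólya-Gamma Gibbs sampler

PG(1, z) augmentation converts the logistic likelihood to a conditionally
Gaussian form: e^{yz}/(1+e^z) = (1/2) e^{κz} E_W[e^{−W z²/2}] with
κ = y − 1/2 and W ~ PG(1, 0). One sweep:

1. **W_ij ~ PG(1, |ζⱼ + βⱼ η_ij|)** at the current linear predictor.
2. **ζⱼ | ·** ~ N(m, V), V = (σ_ζ^{−2} + ∑ᵢ W_ij)^{−1},
   m = V (μ_ζ σ_ζ^{−2} + ∑ᵢ (κ_ij − W_ij βⱼ η_ij)).
3. **βⱼ | ·** ~ N(m, V) truncated to (0, ∞),
   V = (σ_β^{−2} + ∑ᵢ η_ij W_ij)^{−1},
   m = V (μ_β σ_β^{−2} + ∑ᵢ η_ij (κ_ij − W_ij ζⱼ)); η² = η since η is
   binary. Truncated draws use scipy's `truncnorm` (robust in the far-tail
   regime where naive inverse-CDF sampling degrades).
4. **α_i | ·**: categorical over the C patterns with log-weights
   log π_c + ∑ⱼ [κ_ij z_jc − W_ij z_jc²/2], z_jc = ζⱼ + βⱼ η_cj. This is
   the exact conditional: the auxiliary density tilts as
   f(W|z) = cosh(z/2) e^{−Wz²/2} p(W|1,0); the PG(1,0) base density cancels
   in the normalization and Bernoulli(y; logistic(z)) · cosh(z/2) = e^{κz}/2.
   The test suite verifies this identity against a direct evaluation of the
   unsimplified form to 1e−10. An optional `collapsed=True` mode drops the
   W term (plain Bernoulli-likelihood weights); it is off by default.
5. **π | ·** ~ Dirichlet(δ₀ + n₁, …, δ₀ + n_C).

Every draw is exact — no accept/reject step and no tuning parameters.

**PG(1, z) generation.** The generator implements Devroye's exact
alternating-series rejection sampler for the Jacobi-type J*(1, z/2)
distribution (PG(1,z) = J*(1, z/2)/4), with the truncated-inverse-Gaussian /
truncated-exponential proposal mixture split at t = 0.64. Acceptance is
uniformly above ~99%, so cost is O(1) per draw; the inner loop is
numba-compiled and consumes a `numpy.random.Generator`, giving ~10⁷ draws/s
on one core and full seed reproducibility. The defining truncated
sum-of-gammas representation (200 terms) is kept in the test suite as an
independent distributional oracle (two-sample KS), never used in
production. Closed-form mean tanh(z/2)/(2z) and the Laplace transform
cosh(z/2)/cosh(√(z²+2t)/2) are checked by Monte Carlo.

**Step order and timing.** The sweep runs 1→5 as listed; the class update
(step 4) uses the W drawn in step 1 (at the pre-sweep classes) together with
the freshly drawn ζ, β. W is not re-drawn between steps.

**Initialization.** ζⱼ ← logit of the item mean of Y (clipped to
[0.05, 0.95]), βⱼ ← 1, classes uniform at random, π uniform. With multiple
chains, starts are overdispersed by adding N(0,1) jitter to ζ and β (β
floored at 0.05). Chain c uses `default_rng(seed + c)`; runs are bit
reproducible. Constant item columns are not special-cased (the prior
dominates and the sweep proceeds).

**Storage.** Post-burn-in, thinned draws of (ζ, β, π) are stored densely;
latent classes are stored as per-examinee class-frequency accumulators
(N×C), which is all the MAP-pattern and marginal-mastery summaries need and
bounds memory at large chain lengths; full class draws are optional.

**Priors.** Defaults are diffuse: ζⱼ ~ N(0, 10⁵), βⱼ ~ N(0, 10⁵)I(β>0),
π ~ Dirichlet(1,…,1). The pre-configured studies center the (equally
diffuse) item priors at the condition's true values, matching the reference
study protocol; with variance 10⁵ the center is numerically irrelevant.

## Metropolis-Hastings baseline

Item-wise random-walk MH: ζⱼ′ ~ N(ζⱼ, σ_ζ²) accepted with the likelihood ×
prior ratio; then βⱼ′ ~ N(βⱼ, σ_β²) truncated at 0, with the proposal
correction Φ(βⱼ/σ)/Φ(βⱼ′/σ) in the ratio. ζ and β are updated sequentially
with separate accept/reject decisions (matching the per-parameter proposal
notation of the reference tunings). The latent classes and π use the same
Gibbs blocks as the PG sampler but with plain Bernoulli class weights — the
MH scheme involves no auxiliary W. The two reference tunings are proposal
*variances* 0.1 and 1 (`MHProposalSpec.from_variances`); this sd-vs-variance
reading matters and is deliberately explicit in the API. Because η is
binary, each item's likelihood reduces to four sufficient statistics, making
the per-item update O(1). Proposal scales are never adapted: the baseline
exists to show the cost of manual tuning.

The suite cross-validates the two samplers: on a shared N=300, J=10, K=2
dataset their ζ/β EAPs agree within 0.05, and on a one-item toy model both
match a 3-D quadrature of the exact posterior within 0.02. A Geweke-style
successive-conditional test checks that one full Gibbs sweep preserves the
prior marginals of (ζ, β, π) on a tiny model.

## Diagnostics and summaries

PSRF uses the Brooks–Gelman corrected form
R² = ((n−1)/n + B/(nW))·(m+1)/m − (n−1)/(mn) across whole, separately
started chains — no split-halving (available but off) and no rank
normalization, matching the era of the diagnostic as it is used with
4 overdispersed chains and a 1.1 threshold. Note the corrected statistic is
bounded below by √((n−1)/n), slightly *below* 1; the implementation does not
clip it. π is monitored per coordinate. Zero within-chain variance returns
+∞ with a warning. The PSRF trace evaluates the statistic cumulatively on
the first g iterations over a default grid of 20 checkpoints (the reference
plots do not state their grid).

Summaries: EAP (mean), SD (n−1 denominator), and the HPDI as the shortest
window of the sorted draws containing ⌊level·n⌋+1 points, ties broken to
the smallest lower bound. For 100 equally spaced draws at level 0.95 this
is a 96-point window, the usual discrete convention (as in e.g. arviz);
HPDIs of skewed posteriors may legitimately exclude the mean, so only
lower ≤ upper and the coverage count are guaranteed.

## Simulation engine and study designs

`generate_dataset` draws classes from π (flat by default), then
Y_ij ~ Bernoulli(gⱼ + (1−sⱼ−gⱼ)η_ij). The four named noise levels are
LNL (s=g=0.1), HNL (s=g=0.2), SHG (0.2, 0.1), GHS (0.1, 0.2). The reference
design uses the built-in 30-item, 5-attribute Q-matrix (two unit rows per
attribute, all ten attribute pairs, nine triples, and a duplicated (0,0,0,1,1)
row — reproduced verbatim from the reference design, duplicate included);
it satisfies the Gu–Xu conditions.

Metrics: Bias and MSE of EAPs across M replicate datasets (per parameter,
then averaged across items or classes); CPCR (exact pattern match rate) and
AAMA (per-attribute match rate) from per-examinee point estimates — by
default the modal posterior class (MAP), with a 0.5-thresholded marginal
rule as the documented alternative; the two agree whenever one class holds
a posterior majority.

Study scales:

- **full**: 25 replications, 20,000 iterations, 10,000 burn-in, 4 chains —
  the reference protocol, hours of compute;
- **reduced** (default): 5 replications, 4,000 iterations, 2,000 burn-in,
  1 chain — identical structure at desk scale. One chain suffices here
  because all study metrics are EAP-based; multi-chain PSRF convergence is
  exercised separately. Study 4 defaults to a single replication (its rates
  are already averages over N×K judgements). Replicate r of a study seeded
  with σ simulates with seed 1000σ + r and fits with seed 1000σ + 500 + r,
  so every table is reproducible from one integer.
- Study 3 (prior sensitivity: types I–IV with prior variance 0.5, 1, 10³,
  10⁵ centered at truth) fits the *same* replicate datasets under every
  prior type — a paired design that isolates the prior effect from
  sampling noise at small replication counts.

What the generator does *not* emulate: real assessments have heterogeneous
item parameters, correlated attribute prevalences (not flat π), and
Q-matrix misspecification. Passing recovery tests here demonstrates
correctness of the sampler under the model, not robustness to model
misfit.

## Relation to published reference values

Two families of printed reference numbers are **not attainable by any
correct implementation of the stated design**, and this package's tests
leave them red rather than matching them:

- *Low-noise parameter MSEs.* Under flat π, a unit-vector item has ~N/2
  examinees in the η=0 group, so var(ζ̂ⱼ) ≥ 1/(0.5N·g(1−g)) ≈ 0.022 at
  N=1000, g=0.1 — the Cramér–Rao floor. The printed low-noise averages
  (0.0048 for ζ, 0.0141 for β) sit several-fold below this floor. This
  package measures ≈ 0.022/0.10, and an independent marginal-ML EM fit of
  the same data measures ≈ 0.022/0.08 — mutually consistent and
  information-bound-consistent. The printed *high-noise* ζ MSE (0.0163)
  is consistent with the bound and is reproduced (≈ 0.012–0.014).
- *Low-noise classification rates.* The Bayes-oracle classifier (true
  parameters, true π, MAP class) attains CPCR ≈ 0.915 / AAMA ≈ 0.980 under
  LNL at this design (measured at N=200,000); the printed 0.8740/0.9693 are
  four points below oracle, and the printed SHG/GHS gap (0.748 vs 0.844)
  contradicts the near-symmetry of the oracle rates (0.827 vs 0.825). This
  sampler performs at oracle level, as a correct implementation should.

The published empirical-analysis tables hint at the cause: their interval
endpoints cluster at exactly −2.5/−1.0 (ζ) and 2.5/4.5 (β), indicating a
hard-truncated parameter space around the true values in the reference
implementation. Truncating β at 4.5 — half a logit above the true 4.3945 —
also reproduces the otherwise puzzling uniform β bias of ≈ −0.108. No such
truncation is part of the stated model, so this package does not implement
it.

## Numerical notes and limitations

- PG draws dominate runtime (N·J per sweep); a 4,000-iteration fit at
  N=1000, J=30 takes ~20 s on one core. All other blocks are vectorized
  (two N×C GEMMs for the class weights, row-wise inverse-CDF categorical
  draws).
- Only PG(1, z) is provided (all that binary responses need); b ≠ 1, DINO /
  rRUM / LCDM variants, polytomous responses and missing data are out of
  scope.
- Degenerate generator settings (s = g = 0) are allowed for testing the
  generator itself but have no logit-scale truth.
- Under the default var-10⁵ priors, βⱼ is only weakly identified above the
  point where P(Y=1|η=1) saturates: if the observed η=1 group of an item
  happens to contain no incorrect answers (likely for multi-attribute items
  at small N), the likelihood is flat in βⱼ beyond ~6 and draws random-walk
  far into the prior; the class update can then make the configuration
  quasi-absorbing by keeping slipping examinees out of the group. This is a
  property of the model with near-pure groups, not of the sampler — use a
  moderately informative β prior or larger N when multi-attribute items
  have small mastery groups. Convergence checks use N = 1000, where the
  reference design is well-identified.
- The categorical row sampler breaks ties by cumulative order; HPDI ties go
  to the smallest lower bound; `argmax` MAP patterns break ties to the
  lowest class index. All are deterministic given the seed.
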