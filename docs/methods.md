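# Methods

This note documents the models, the synthetic study design, the
numerical choices, and the limitations of `hccstem`. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## One-class stemness model (OCLR)

Training data are log2 expression profiles of a reference compendium
containing stem and differentiated samples. Each gene is centered by
its mean over the **full** compendium, and the one-class logistic
objective

J(w) = −(1/n) Σᵢ log σ(wᵀxᵢ) + λ₁‖w‖₁ + (λ₂/2)‖w‖₂²

is minimised over the **stem subset only**, without an intercept.
Centering by the full compendium is not cosmetic: if the training
subset centered itself, the gradient of the smooth part at the origin,
−(1/2)·mean(xᵢ), would vanish, making w = 0 the exact penalised
optimum and the model vacuous. Centering against the broader
compendium is the only coherent reading of a one-class model meant to
contrast stem against non-stem expression, and the package tests both
facts (w = 0 on self-centered data; informative weights otherwise).

*Solver.* Proximal gradient descent with fixed step 1/L,
L = σ_max(X)²/(4n) + λ₂ (the logistic Hessian bound plus the ridge
term). The objective is monotonically non-increasing; convergence is
declared when the inf-norm of the minimal-norm subgradient falls below
`tol`. Defaults: λ₁ = 0, λ₂ = 1, tol = 1e−6, max_iter = 10000. The
elastic-net penalties are exposed because the reference-compendium
scale, not the method, should drive their choice; with λ₂ ≥ 1 the
problem is strongly convex and the solver converges linearly. Tests
verify the solution against an independently coded tiny-step proximal
loop (≤ 1e−4 sup-norm on 20-gene problems) and against a 1-D
bisection root in the single-gene case.

*Scoring.* mRNAsi_i = rescaled Spearman ρ(w, xᵢ) over the genes shared
between model and cohort (≥ 50 % of model genes required; average
ranks on ties). Rescaling is min–max **within the scored cohort**,
matching an index defined to span [0, 1] per cohort; because this
makes any fixed cutoff cohort-relative, `score_mrnasi` also accepts
fixed `rescale_bounds` for cross-cohort comparability. Being
rank-based, the index is invariant to any strictly increasing
per-sample transform of expression (tested).

## Synthetic study design

The generator emulates the statistical structure the analysis assumes,
at desk scale; every generator operation draws from its own RNG stream
keyed by `(seed, operation name)`, so outputs are bit-reproducible and
adding operations never perturbs earlier draws.

- **Reference compendium** (default 1000 genes × 60 stem + 60
  differentiated): per-gene baseline means ~ Normal(8, 2) drawn once,
  i.i.d. Normal noise (sd 1). A planted program of 80 genes is shifted
  by ±`stem_effect` in stem samples — half up, half down. The signed
  program mirrors real stemness signatures (stemness markers rise,
  differentiation markers fall) and is load-bearing: a uniformly
  up-shifted program is invisible to the 1 − Pearson sample distance
  used downstream, because per-sample centering removes any constant
  shift across genes.
- **Tumor cohort** (default 150 samples): latent stemness
  sᵢ ~ Uniform(0, 1) shifts program genes by ±sᵢ·`stem_effect`.
  Non-response is Bernoulli(σ(−5.0 + 16.0·sᵢ)); these two constants
  were fitted so the logistic link reproduces, simultaneously, a
  46/67 overall non-response rate and subgroup non-response rates of
  2/19 and 44/48 — the count structure of the drug-response cohort the
  module emulates. Survival is exponential with hazard
  (ln 2/30)·exp(`hazard_coef`·sᵢ) (baseline median 30 months,
  proportional hazards by construction so Cox recovery is well-posed);
  a `censor_rate` fraction of samples is administratively censored at
  a uniform fraction of their event time.
- **Panel chain**: four genes named for the pathway panel they emulate
  (RXRB → NR1H3 → CYP8B1 → SCD) follow a linear-Gaussian chain with
  coefficients `chain_coefs` and a `panel_shift` mean shift of the
  root in non-responders. Linear-Gaussian structure makes BIC-based
  structure learning consistent and the (v-structure-free) chain's
  skeleton identifiable; the Markov property (G1 ⟂ G4 | G2, G3) is
  tested on the generated data.
- **Gene sets**: one pathway-like set (panel + program), one pure-noise
  set, eight random sets; written/read as standard GMT.

`stem_effect` defaults to 4.0: the median split halves the uniform
latent gradient, so the expected between-subgroup fold change of a
program gene is `stem_effect`/2, and the default must clear the 1.5
log2FC DEG threshold with margin for the planted program to behave
like the study's DEG set in the end-to-end run. Recovery tests use
`stem_effect` = 2 to show the index does not need the larger effect.

*What the generator does not emulate:* count-level noise
(negative-binomial mean–variance), batch effects, correlated
background genes, non-proportional hazards, or informative censoring.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated model, not robustness to those
real-data pathologies.

## Subgroups

- Median split: strictly greater than the cohort median ⇒ `high`
  (ties fall to `low`).
- Differential expression: per-gene Welch t on log2 values with BH
  adjustment. This deliberately replaces the moderated-t of the
  limma-style pipeline the analysis descends from: empirical-Bayes
  variance shrinkage matters most at very small n, and replicating it
  was out of scope. Thresholds (|log2FC| > 1.5, adj. p < 0.01) are kept
  identical. Zero-variance genes with equal means get p = 1.
- Consensus clustering (Monti resampling): per repetition, ⌈0.8·n⌉
  samples are drawn; hierarchical clustering with
  d(i,j) = 1 − Pearson(xᵢ, xⱼ) (computed once on the full cohort —
  pairwise correlations do not depend on which other samples are
  resampled — then subset), average linkage, cut at each k in 2..6.
  consensus(i,j) = co-clustered / co-sampled. Genes are z-scored
  before the distance by default (configurable), since the DEG matrix
  mixes baseline scales. The consensus-CDF area A(k) equals
  1 − mean(consensus entries); the chosen k is the smallest whose next
  relative delta-area falls below 0.1 (configurable). Final labels
  cluster 1 − consensus at the chosen k. In the pipeline, clusters are
  mapped to `high`/`low` by comparing each cluster's mean mRNAsi to
  the cohort median — clusters segment the stemness gradient, so a
  mean-vs-median rule bisects them stably even when k > 2.
- Association: per subgroup, chi-square goodness-of-fit of
  (responders, non-responders) against equal proportions, df = 1, no
  continuity correction — chosen because it exactly reproduces both
  published per-subgroup p-values from the reconstructed count table;
  plus an overall Pearson chi-square.
- Wilcoxon rank-sum comparisons across response groups use Hommel
  adjustment, validated against an exhaustive closed-testing (Simes)
  enumeration for m ≤ 5.

## Enrichment

ORA: hypergeometric upper tail P(X ≥ k) with sets intersected against
the universe first, BH across sets. The p-value is discrete and hence
conservative (super-uniform) under the null; the calibration test
checks validity of the actual p and exact uniformity of its randomized
version.

Preranked GSEA: descending sort by statistic (log2FC in the pipeline);
running sum gains |stat|^α/Σ_hits|stat|^α at members (α = 1 default)
and loses 1/(N−K) at non-members; ES is the extremum by absolute
value. The null is size-matched random gene sets (the ranking is a
single preranked vector, so phenotype permutation is unavailable);
NES = ES / mean(|null ES| of matching sign); p is the matching-sign
exceedance fraction, floored at 1/(n_perm+1) with its Monte-Carlo SE
reported. Overlap bounds 3–500, configurable.

## Bayesian networks

Pathway activity = mean of member-gene z-scores (simple, monotone,
variance-stabilised; constant genes dropped, pathways with < 3
measured members skipped). Structure learning is greedy hill climbing
over add/delete/reverse moves maximising the decomposable Gaussian
BIC (per-node OLS log-likelihood − (k/2)·log n), acyclicity enforced
per move, max 3 parents, first restart from the empty graph and
further restarts from random DAGs; node scores are cached. An exact
dynamic-programming search over variable orderings (≤ 6 nodes) serves
as the global-optimum oracle in tests. Bootstrap confidence: R
resamples with replacement (desk default R = 200; the study-scale
setting R = 10000 is a config value), edge strength = fraction of
resamples containing the edge in either direction,
direction_confidence = majority-orientation fraction, consensus at
strength ≥ 0.5. A chain without v-structures is only identifiable up
to its Markov-equivalence class, so tests assert skeleton recovery and
score optimality, not orientation.

## Signature and ROC

Panel genes are standardized (mean/sd of the fitting cohort) and the
top-2 right singular vectors of the samples × genes matrix give the
loadings; coordinates are plain projections (not eigenvalue-scaled),
and PPARscore = Dim1 + Dim2. Each component's sign is fixed by making
its largest-|loading| entry positive — without a sign convention the
score, and any published cutoff on it, is meaningless. New cohorts are
projected with the stored standardization and loadings (a six-sample
validation cohort cannot support a stable refit); a refit is always
available by calling `fit_signature` on the new cohort. AUC uses the
Mann–Whitney identity with ties counted ½; the operating cutoff
minimises (1 − sens)² + (1 − spec)², ties broken by higher
sensitivity then lower threshold; classification is strict:
score > cutoff ⇒ predicted non-responder. The module retains the
published cutoff constant (−0.56) as the default for
`classify_response` on real cohorts; synthetic runs use the
ROC-derived cutoff.

## Survival

The 5-year rule is implemented as administrative censoring at 60
months (event set to 0 at the horizon) rather than exclusion of
longer-lived patients, which would condition on the outcome; an
`exclude` mode exists for comparison. KM is the product-limit
estimator with Greenwood standard errors; the two-group log-rank uses
the standard O−E statistic (df = 1). Cox fitting starts from a
lifelines solve and then Newton-polishes on an own-coded Efron
score/Hessian until the gradient inf-norm is below 1e−8, with Wald
CIs/p-values from the polished information matrix — the polish exists
because the upstream solver's default stopping rule leaves the score
at ~1e−6, short of the accuracy the tests demand. The classical
identity (Cox score test at β = 0 = log-rank for a binary covariate
without ties) is verified to 1e−8 with a separately coded score
statistic.

## Pipeline

`run_full_pipeline` executes simulate → train/score → median split →
DE → consensus → association → ORA/GSEA → pathway & gene networks →
signature/ROC → survival, writing tab-separated tables and JSON plus a
manifest with SHA-256 hashes, parameters and the seed. A single global
seed is fanned out deterministically per stage (stage seeds =
f(seed, stage name), each < 2³¹), so stages are independently
re-runnable and the whole run is byte-reproducible. Any stage failure
aborts with the stage name after persisting the partial manifest.
Desk-scale problem sizes throughout (10³ genes, ~10² samples,
R = 200 bootstraps, 1000 consensus repetitions) keep a full run in
seconds while leaving every algorithmic path identical to a full-scale
run.

## Known limitations

- Welch t is not moderated t; at very small group sizes its DEG lists
  will differ from an empirical-Bayes pipeline.
- Per-cohort min–max rescaling makes fixed mRNAsi cutoffs (0.55)
  cohort-relative; whether such a cutoff transfers across cohorts is
  an empirical claim the package exposes but cannot settle.
- Preranked GSEA with gene-set permutation ignores inter-gene
  correlation, as all preranked approaches do.
- BN orientations within Markov-equivalence classes are conventions of
  the search order, not inferences.
- The synthetic generator's Gaussian log2 model understates the
  heavy-tailed, correlated noise of real expression data; quantitative
  recoveries reported by the acceptance script are upper bounds on
  what identical settings would achieve on real cohorts.
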