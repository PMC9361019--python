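# hccstem

Transcriptomic stemness-index analysis for tumor cohorts, built around
the question that motivates it in hepatocellular carcinoma (HCC): does
the degree of tumor *dedifferentiation* — how stem-cell-like a tumor's
expression profile is — predict resistance to sorafenib and worse
survival, and which pathways carry that resistance?

The package is a library first (every stage is an importable function
with a documented contract), with a thin `hccstem` CLI for running
stages or the whole pipeline from a shell, and a first-class synthetic
data module so the entire analysis is exercisable and testable without
any external download.

## The model

**Stemness index (mRNAsi).** A one-class logistic regression (OCLR) is
trained on stem-cell reference samples only. With `x_i` the centered
expression profile of reference sample `i` (per-gene means taken over
the *full* compendium, stem + differentiated), the per-gene weight
vector `w` minimises

    J(w) = -(1/n) Σ_i log σ(wᵀx_i) + λ₁‖w‖₁ + (λ₂/2)‖w‖₂²

with no intercept (σ the logistic function; solved by proximal
gradient descent, certified by the subgradient norm). A cohort sample's
raw score is Spearman's ρ between `w` and its expression over the
shared genes; min–max rescaling within the cohort gives the mRNAsi in
[0, 1]. Higher mRNAsi = less differentiated.

**Subgroups and response.** The cohort is split at the median mRNAsi;
Welch-t differential expression (|log2FC| > 1.5, BH-adjusted p < 0.01)
defines DEGs; Monti-style consensus clustering of DEG expression
(1000 subsampling repetitions, 1 − Pearson distance, average linkage,
cluster number from the consensus-CDF delta-area rule) defines the
final subgroups, which are tested against the drug-response label by
chi-square (per-subgroup goodness-of-fit and overall).

**Pathways and regulation.** Hypergeometric over-representation
analysis and preranked GSEA (gene-set permutation null) identify
enriched pathways from the DEGs and the log2FC ranking; bootstrap
Bayesian-network structure learning (Gaussian-BIC hill climbing on
resampled cohorts, edge strength = resample frequency) infers
regulatory structure among pathway activities and among the four-gene
panel RXRB, NR1H3, CYP8B1, SCD.

**Response signature.** PCA on the standardized four-gene panel gives
per-sample coordinates Dim1, Dim2 and `PPARscore = Dim1 + Dim2`; the
ROC point closest to (0, 1) sets the cutoff, above which a sample is
predicted resistant.

**Survival.** Cohorts stratified at an mRNAsi cutoff (default 0.55)
are compared over a 60-month horizon by Kaplan–Meier/log-rank and a
Cox proportional-hazards fit (Efron ties, Newton-polished to a 1e-8
score tolerance).

## Worked example

```bash
python examples/02_stemness_index.py
```

prints (seed 1, reduced-scale simulated study):

```
OCLR converged in 464 iterations (objective 0.0424, subgradient 9.9e-07)
Spearman(latent stemness, mRNAsi) = 0.954
AUC(mRNAsi vs non-response)      = 0.943
```

The simulation plants a latent stemness level per tumor sample; a
Spearman correlation of 0.95 says the trained index recovers that
ordering almost perfectly, and the AUC of 0.94 says the index predicts
the simulated sorafenib response about as well as the latent truth
allows. The remaining examples walk each capability —
`03_subgroups_and_response.py` ends in the subgroup × response
contingency table with its proportion-test p-values,
`05_regulatory_network.py` prints the bootstrap edge table that
recovers the planted RXRB → NR1H3 → CYP8B1 → SCD chain skeleton, and
`08_full_pipeline.py` runs everything end-to-end into a manifest of
byte-reproducible outputs. The same pipeline runs from the shell:

```bash
hccstem run-all --seed 11 --outdir out/
```

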