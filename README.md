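# sharedarch

Joint **phenotypic** and **genetic** analysis of shared architecture between
two trait blocks (e.g. mental-health questionnaire scores and accelerometer
activity summaries, each against resting-state brain network measures) —
implemented as a fully tested pipeline over **synthetic data with known
ground truth**.

## What it does

**Phenotypic arm** (individual-level tables):

1. drop questionnaire items with >30% missingness,
2. chained predictive-mean-matching imputation (20 iterations, 5 donors,
   averaged), multinomial imputation + dummy coding for categoricals,
3. PCA of items, retaining components that cumulatively explain >50%
   variance,
4. FDR-corrected Pearson correlations between component scores and activity
   measures,
5. confound residualization, then four canonical correlation models
   (simple / "unique" x two behavioural sides) with step-down Wilks
   permutation inference (1000 permutations), per-variable loading
   permutation tests pooled across significant variates, and cross-model
   variate matching.

**Genetic arm** (GWAS summary statistics + LD scores):

1. LD-score regressions — SNP heritability and pairwise genetic correlation
   with block-jackknife SEs, assembled into a genetic covariance matrix S
   with a joint jackknife sampling covariance V,
2. one-common-factor model on S (DWLS, CFI / SRMR, sandwich chi-square),
   plus factor–external-phenotype genetic correlations with a declared
   10-test FDR family,
3. latent-causality screening: genetic causality proportion (GCP) from
   LD-weighted mixed higher moments, with jackknife inference.

**Synthetic generators** (`sharedarch.syndata`) plant exact ground truth:
cohorts whose population canonical correlations equal the requested values
(closed-form loading construction, analytic oracle provided), and summary
statistics obeying the LD-score moment model with configurable
heritabilities, genetic correlation, sample-overlap intercept, and latent
causal architecture.

## CLI

```bash
sharedarch simulate-cohort --n-subjects 6000 --rhos 0.25,0.15 --seed 1 --out cohort/
sharedarch simulate-sumstats --h2 0.1,0.1 --rho-g 0.012 --seed 1 --out gwas/
sharedarch impute cohort/mh_items.tsv --out imputed.tsv
sharedarch pca imputed.tsv --out scores.tsv
sharedarch cca cohort/brain.tsv cohort/pa.tsv --confounds cohort/confounds.tsv \
    --n-perm 1000 --seed 1 --out cca.json
sharedarch ldsr h2 gwas/trait1.sumstats --ld gwas/ld_scores.tsv
sharedarch ldsr rg gwas/trait1.sumstats gwas/trait2.sumstats --ld gwas/ld_scores.tsv
sharedarch lcv --trait1 gwas/trait1.sumstats --trait2 gwas/trait2.sumstats \
    --ld gwas/ld_scores.tsv
sharedarch run-all config.yaml --out run/       # both arms from one YAML
```

## File formats

Everything is plain text: phenotype tables as TSV (empty field = missing)
with a JSON sidecar for variable kinds and generative truth; summary
statistics as whitespace-delimited `SNP A1 A2 Z N`; LD scores as TSV
`SNP L2`; reports as JSON + TSV matrices.
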