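# serometa

Case–control serum metabolomics analysis: quality control and normalization
of a relative-abundance matrix, covariate-adjusted empirical-Bayes moderated
differential abundance, metabolite-group (pathway) enrichment, and
differential co-abundance analysis with binomial group enrichment — plus a
synthetic cohort generator with planted ground truth that makes every stage
testable without access to patient data.

The package targets studies like a serum metabolomics comparison of Macular
Telangiectasia type 2 (MacTel) patients against healthy controls: ~60 cases
and ~58 controls, ~950 metabolites measured as relative abundances on an
LC-MS platform, metabolites organized into ~50 KEGG-like metabolic groups,
below-detection-limit missingness, and demographic covariates (sex, age,
diabetes, ethnicity, BMI, collection site) that must be adjusted for.

## Methods at a glance

**Preprocessing** (in this fixed order): drop metabolites with > 20% missing
values (the "80% rule"); impute remaining missing cells with the
per-metabolite observed minimum (a left-censoring surrogate); report
subjects outside the Tukey fences of per-subject missingness;
quantile-normalize between samples; scale each metabolite to zero mean and
unit SD; PCA for visual covariate QC.

**Differential abundance.** Each metabolite *j* is fit by OLS,

    y_j = β0 + β_j·status + γ'·covariates + ε,   ε ~ N(0, σ_j²),

and the residual variances s_j² are shrunk toward a pooled prior (d0, s0²)
estimated by method of moments on log s²:

    s̃_j² = (d0·s0² + d·s_j²) / (d0 + d),

with the moderated statistic t_j = β̂_j / (c·s̃_j) referred to t(d + d0).
Benjamini–Hochberg FDR at 0.05. The reported logFC is the status
coefficient on the quantile-normalized log2 scale (a paired run), with the
unit-variance coefficient emitted alongside.

**Group enrichment.** A self-contained rotation test: group statistics
(mean and mean-of-squares of moderated t) are referred to a null built by
random rotations of the fitted model's residual space, preserving
within-group correlation. Groups whose members move in opposite directions
are additionally represented by their first principal component and tested
with the same linear model.

**Differential co-abundance.** Metabolites are residualized on covariates +
status; Pearson correlations are computed within cases and within controls;
pairs with max(|r_case|, |r_control|) ≥ 0.5 (xenobiotics excluded) are
tested with the two-sample Fisher r-to-z statistic

    z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)),

BH-corrected at FDR 0.1, and classified lost/gained × positive/negative.
Each metabolic group then gets an exact one-sided binomial test with
success probability p_parameter = (significant pairs)/(tested pairs),
BH-corrected at FDR 0.05.

## Worked example

```bash
printf 'simulate: true\nseed: 1\n' > cfg.yaml
serometa run-all --config cfg.yaml --out run1
```

This simulates the default cohort (118 samples × 946 metabolites, planted
glycine–serine depletion, phosphatidylethanolamine elevation, sphingomyelin
depletion, and control-only sphingomyelin cross-group correlations), runs
every stage, and logs:

```
simulated cohort: 118 samples x 946 metabolites (seed=1)
missingness filter: dropped 179 of 946 metabolites
differential abundance: 5 significant of 767 (d0=inf)
set analysis: 50 groups tested, 0 skipped
co-abundance: 232 significant of 5064 tested pairs (p_parameter=0.04581)
```

The top of `run1/group_enrichment.tsv` recovers the planted groups
(rotation q, then PC1 p):

```
group                                direction  p_mixed  q        pc1_p
phosphatidylethanolamines            up         0.0001   0.0050   0.000153
glycine_serine_threonine_metabolism  down       0.0008   0.0200   0.002160
sphingomyelins                       down       0.0085   0.1417   0.009016
```

and `run1/coabundance_enrichment.tsv` flags the decoupled groups:

```
group                                k    n    p             enriched
sphingomyelins                       183  389  1.6e-134      True
glycine_serine_threonine_metabolism  137  226  2.0e-121      True
phosphatidylethanolamines            46   129  1.3e-28       True
```

k of n tested pairs touching each group are significantly differentially
co-abundant; under the global rate (p_parameter ≈ 0.046) these counts are
wildly enriched — the planted control-only correlations were recovered.
Note the per-metabolite significant count (5 of 767) is attenuated by
left-censoring + minimum imputation; the uncensored recovery study (below)
shows the estimator itself is unbiased. Rerunning with the same config and
seed reproduces every table byte-identically (see `run1/manifest.json`).

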