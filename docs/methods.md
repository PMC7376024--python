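# Methods

This note documents the statistical model behind each pipeline stage, the
tunable parameters and their defaults, what the synthetic cohort generator
does and does not emulate, and the numerical and design choices that were
genuinely open.

## Data model

The central object is a samples × metabolites matrix of (log2) relative
abundances with an explicit boolean missingness mask and a processing-state
flag (`raw → filtered → imputed → normalized → scaled`). The mask survives
imputation so original missingness stays auditable; the state flag makes the
QC order a hard contract rather than a convention. Metadata carries disease
status and the adjustment covariates (sex, age, diabetes, ethnicity, BMI,
collection site); annotation maps each metabolite to exactly one metabolic
group and a super-class, with xenobiotics flagged.

Missing cells in input files are empty cells or `NA` (configurable), since
vendor exports vary. Matrix orientation (samples or metabolites in rows) is
declared by the caller. All result tables are plain long-format TSV with a
stable column order so runs can be diffed bit-exactly.

## Preprocessing

* **80% rule.** Metabolites missing in strictly more than `max_missing`
  (default 0.20) of samples are dropped. Filtering precedes imputation:
  imputed minima on heavily censored metabolites otherwise dominate the
  principal components. In a 946-metabolite study with the default censoring
  regime this removes roughly 180–200 metabolites. (A study reporting
  946 measured and 738 surviving metabolites has removed ~14 more than the
  80% rule accounts for; only the described filter is implemented here, so
  exact survivor counts are not expected to match any particular dataset.)
* **Minimum imputation.** Missing values indicate levels below the
  platform's detection limit, so each masked cell receives the metabolite's
  minimum observed value. A metabolite with no observed values is a hard
  error. Probabilistic left-censored imputation is out of scope.
* **Missingness outliers.** Subjects outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of per-subject missing fractions are
  *reported*, not removed; exclusion is an explicit opt-in
  (`exclude_missingness_outliers`), since a well-matched cohort typically
  excludes nobody.
* **Quantile normalization** equalizes the per-sample value distributions
  (rank-wise means). Ties receive the exact average of the reference values
  their rank positions would imply, which makes the operation deterministic
  and symmetric; the transform is idempotent to 1e-10. Inputs already on the
  log2 scale are normalized directly; a `log2_transform` config toggle
  handles raw-scale exports.
* **Scaling** to zero mean and unit SD per metabolite uses the n−1
  denominator; a zero-variance metabolite is an error naming the column.
* **PCA QC** emits sample scores on the first two components joined to all
  covariates, for visual confirmation that no covariate dominates the
  post-normalization structure.

## Differential abundance

Per-metabolite OLS on status plus covariates; categorical covariates are
one-hot encoded against the most frequent level (a deterministic choice the
underlying model leaves open). Collection site is included as a covariate by
default and removable via config. The variance prior (d0, s0²) is estimated
by method of moments on log s²: the excess of var(log s²) over its
χ²-sampling expectation trigamma(d/2) identifies d0 through the inverse
trigamma function; no excess gives d0 = ∞ and s̃² ≡ s0² = mean(s²). The
implementation reproduces the Bioconductor limma `eBayes` hyperparameters
and moderated statistics to ~1e-12 on shared fixtures (verified in the test
suite with limma as an independent oracle). `prior_df=0` switches moderation
off exactly, recovering per-metabolite ordinary t-tests.

Two scales are emitted per metabolite, clearly labelled: `logFC`, `ci_low`,
`ci_high` from the run on the quantile-normalized log2 matrix (log2 units,
the interpretable effect size), and `logFC_scaled`, `t_mod`, `p`, `q` from
the unit-variance run (where variance moderation pools comparable
quantities). On scaled data the residual variances are nearly homogeneous by
construction, so d0 is typically estimated as infinite — moderation then
amounts to full pooling.

A `subset` config filter reruns any stage on a metadata-defined stratum
(e.g. one ethnicity), the generic form of a sensitivity reanalysis.

## Group enrichment

The rotation test works in the orthonormal basis of the design: after a QR
decomposition with the status column last, each metabolite reduces to one
signed effect component u0 and d = n − p residual components. A rotation
draws one random unit vector in R^(d+1) and applies it to every metabolite
of the set simultaneously, preserving inter-metabolite correlation; the
moderated t is recomputed with the prior held fixed. Set statistics are the
mean (directional) and mean of squares (mixed) of moderated t; p = (b+1)/
(n_rot+1) never falls below the resampling floor. Defaults: 9,999 rotations,
explicit seed, BH across groups on the mixed p. Groups with fewer than two
measured members are skipped with a warning. Competitive (between-set) and
over-representation tests are out of scope.

The PC1 representation addresses groups whose members shift in opposite
directions: the first principal component of the group submatrix, sign-fixed
to correlate positively with the group's mean abundance and standardized to
unit variance, is tested with the same covariate-adjusted moderated model,
BH across groups. With a single group the moderation prior is undefined and
the test falls back to the ordinary t-test.

Xenobiotic exclusion applies to the co-abundance stage only, not here.

## Differential co-abundance

Residualization regresses each metabolite on covariates *and* status so that
no between-metabolite correlation is created or masked by shared structure;
residuals are orthogonal to every design column to 1e-8. Correlations are
Pearson, computed separately within cases and controls; zero-variance
residual columns in a stratum exclude their pairs with a warning.

Pair retention uses the **either-stratum rule**: keep the unordered pair iff
max(|r_case|, |r_control|) ≥ 0.5. This is the only reading under which both
a "lost" correlation (strong in controls only) and a "gained" one (strong in
patients only) remain testable. Xenobiotic metabolites are removed before
pairing. The Fisher r-to-z statistic uses the per-stratum sample counts
after any subsetting; |r| = 1 is a hard error (infinite transform). BH is
applied within the retained pairs at FDR 0.1. Significant pairs are
classified lost_positive / lost_negative (strong in controls, weak in
cases, signed by the control correlation), gained_* (the mirror), or
changed_other (strong in both).

Group enrichment is an exact binomial test: k = significant tested pairs
touching the group, n = tested pairs touching the group, success
probability = the global significant/tested ratio *recomputed from the data
at hand* (never hard-coded; the published 0.008 is a property of one
dataset). A pair spanning two groups counts once for each. The test is
one-sided (greater) because the hypothesis is enrichment; a two-sided
option is exposed. BH across groups at FDR 0.05.

Two caveats inherent to the method (not defects of this implementation):
pair selection at |r| ≥ 0.5 conditions on observed extremes, so in
low-correlation regimes the retained null pairs are chance extremes and the
FDR within retained pairs is optimistic; and the Fisher test uses nominal
stratum sizes although residualization absorbs ~p degrees of freedom —
measured jointly, the raw type-I error stays within [0.04, 0.06] under the
simulated null.

## Synthetic cohorts

The generator draws log2-scale abundances from a multivariate normal per
disease status and is the package's test bed. Defaults are the target study
conditions; values the study design does not pin down were chosen once as
realistic and are documented here.

* **Cohort**: 60 cases / 58 controls; 946 metabolites in 50 groups (11
  glycine–serine–threonine, 14 phosphatidylethanolamines, 21
  sphingomyelins, 80 xenobiotics, the rest spread over generic groups).
* **Correlation**: compound-symmetric within groups, ρ = 0.7 by default.
  The choice is anchored to the co-abundance regime the method expects: at
  ρ = 0.7 a 738-metabolite cohort yields thousands of tested pairs
  (max |r| ≥ 0.5), the regime in which a global significant/tested ratio of
  order 10⁻²–10⁻³ is meaningful; at low ρ almost no pairs pass retention
  and all retained nulls are chance extremes. Per-group overrides
  (`group_rho`) support mixed regimes.
* **Planted effects** (log2 units, case minus control): glycine −1.31,
  serine −1.03, threonine −0.96, remaining glycine–serine members −0.5;
  all phosphatidylethanolamines +0.8; all sphingomyelins −0.4.
* **Planted decoupling**: cross-group correlation *blocks* — sphingomyelin ↔
  glycine–serine +0.6 and sphingomyelin ↔ phosphatidylethanolamine −0.5 in
  controls, both 0 in cases — emulating group-wide connection loss. Block
  planting is the group-factor model: two metabolites each tightly coupled
  to their own group can only correlate if the groups do, so member-level
  planting of r = 0.6 is infeasible (non-PSD) at ρ = 0.7. The default
  control matrix therefore also carries the consistency completion between
  glycine–serine and phosphatidylethanolamines (−0.43, identical in both
  strata, hence not decoupled). A member-level mechanism
  (`plant_decoupling(..., n_pairs=k)`) exists for studies needing nearly
  independent planted pairs; it requires moderate ρ in the touched groups.
  Both status matrices are eigenvalue-checked and rejected before sampling
  if not positive semi-definite. A consequence of block planting worth
  knowing: all cross pairs of a block share the factor-level sample
  correlation, so the number of significant cross pairs in a default cohort
  swings widely between seeds (from none to several hundred) — the pair
  count is one effective draw, not hundreds of independent ones. The
  calibrated decoupling-recovery claim therefore uses member-level planted
  pairs (below).
* **Covariates**: age ~ N(62, 8²) years, BMI ~ N(27, 4²) kg/m², sex 45% M,
  diabetes 15%, ethnicity 80/10/10%, four collection sites; independent of
  status by default, with an optional case-age confounding knob. Effects
  enter linearly with per-metabolite random coefficients (SDs: age 0.01/yr,
  BMI 0.02, sex 0.15, diabetes 0.2, ethnicity 0.1, site 0.1 on the log2
  scale) — enough structure for covariate adjustment to matter, small
  enough to be realistic for serum metabolites.
* **Left-censoring**: each metabolite is censored below an empirical
  quantile of its own column; ~79.5% of metabolites draw a light quantile
  (U(0, 0.13)) and ~20.5% a heavy one (U(0.22, 0.5)), giving ~13% average
  subject missingness and ~20% of metabolites failing the 80% rule,
  mirroring a realistic platform profile. Censoring is strictly
  left-tailed; the truth record stores every threshold.
* One integer seed fixes every output byte.

**What the generator does not emulate:** LC-MS drift and batch blocks beyond
a single site covariate, heavy-tailed or skewed abundance distributions,
missingness mechanisms other than left-censoring, and correlation structure
richer than within-group compound symmetry plus planted cross blocks.
Passing tests therefore certify the statistical machinery under the stated
model, not robustness to arbitrary real-data pathologies. Note also that
left-censoring + minimum imputation attenuates estimated logFC for strongly
depleted metabolites (the uncensored recovery study isolates estimator bias
from this data-degradation effect; under censoring the bias is reported,
not asserted).

## Validation studies and problem sizes

`serometa.validation` (driven by `scripts/acceptance.py` and the acceptance
tests) runs, with these sizes chosen to give tight Monte-Carlo error at
desk scale:

* moderated-test type-I error: 500 null cohorts × 738 metabolites (369,000
  p-values), band [0.04, 0.06];
* Fisher r-to-z type-I error: ≥ 10,000 within-group residual pairs from
  null cohorts with identical correlation in both strata, band [0.04, 0.06];
* logFC recovery: 200 uncensored default cohorts, mean estimate within
  ±0.05 of every planted value;
* rotation power: a +1 SD whole-group shift (10-group, 100-metabolite
  cohorts), directional p ≤ 0.001 at 9,999 rotations in all of 50 seeds;
* PC1 mixed-direction detection: half-up/half-down group at |1| SD,
  p < 0.05 in ≥ 80% of 200 simulations;
* decoupling recovery: 10 disjoint member-level pairs (r_control = 0.6,
  r_case = 0) between two 10-member groups (ρ = 0.3 within those groups,
  forced by positive semi-definiteness) in a 90-metabolite cohort whose
  remaining groups keep ρ = 0.7 — the touched group must be flagged
  enriched (binomial q < 0.05) in ≥ 80% of 200 seeds. The background size
  matters: the planted pairs' raw p (~2·10⁻⁴ at these r and n) sits near
  the pair-level BH boundary when thousands of null pairs are tested, so
  the study uses a background of ~230 tested pairs.

## Known limitations

* The moderated model assumes approximately normal residuals on the
  (log2, normalized) scale; gross outliers are not down-weighted (no
  robust fitting, no sample quality weights).
* Minimum imputation biases depleted metabolites toward the null; strongly
  censored, strongly depleted metabolites can escape detection.
* The binomial enrichment treats tested pairs as exchangeable; correlated
  pairs within a group violate independence, which the test does not
  correct (a property of the method, inherited deliberately).
* Group definitions come entirely from the annotation file; no counts or
  identities are hard-coded.
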