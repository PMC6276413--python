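# Methods

## Lipid model and derived LDL-c

The package treats TC, HDL-c and TG (mg/dl) as measured quantities and
LDL-c as derived by the Friedewald formula `LDL = TC − HDL − TG/5`,
applicable for TG < 400 mg/dl.  When a table supplies both a measured and
a derivable LDL-c, the derived value wins by default (configurable in
`phenotypes.derive_ldl`): this keeps the four lipids algebraically
consistent, which downstream stages rely on.  Subjects above the TG bound
are flagged invalid rather than refused; exclusion is the caller's choice.

Dyslipidemia cutoffs: TC ≥ 200, LDL-c ≥ 130, TG ≥ 150 mg/dl (all
inclusive), HDL-c < 40 (men) / < 50 (women).  Percentages in prevalence
reports round half away from zero; the unrounded value is always carried
alongside.

## Synthetic cohort generator

Each simulated lipid follows

    lipid_i = b0 + Σ_s e_s[g_is] + Σ_c beta_c x_ic + eps_i,
    eps_i ~ N(0, sigma),

with `e_s` an arbitrary per-genotype triplet (mg/dl for genotypes 0/1/2).
Triplets are deliberately not constrained to be additive so dominance and
heterozygote-advantage architectures can be generated.  LDL-c is never
simulated independently; it is derived from the three simulated channels,
so its causal structure and residual variance are the Friedewald-weighted
combination of theirs.

Genotypes are iid draws per SNP with frequencies
`P(0)=(1−q)²+Fq(1−q), P(1)=2q(1−q)(1−F), P(2)=q²+Fq(1−q)` for MAF `q` and
inbreeding coefficient `F` (F=0 is Hardy–Weinberg equilibrium).

Default conditions (`default_spec`): 304 subjects, 95 SNPs with MAFs
interleaved over [0.05, 0.5], 10 causal SNPs per simulated lipid in
overlapping blocks (so some loci are pleiotropic and most of the panel is
null).  Covariate marginals: age 45.8 ± 10.5 y, BMI 31.6 ± 3.5 kg/m²,
TFAT 36.9 ± 7.6 kg, VFAT 1.48 ± 0.90 kg, energy 2970 ± 934 kcal/d,
macronutrient %E 40.7/17.0/40.4 (carb/protein/fat), cholesterol intake
400 ± 150 mg/d, METs 23.8 ± 20.0, 30% men, 21.9% smokers, 13.5% drinkers —
the profile of an overweight/obese adult cohort.  Covariate slopes follow
the magnitudes such cohorts exhibit (e.g. TC: +0.80 mg/dl per year of age,
+0.38 per 100 kcal; HDL-c: −5.22 per kg VFAT, +5.83 for drinkers); the sex
slope is applied as male = −4.51 mg/dl HDL-c (women higher), since only
the magnitude is identifiable from a summary table without the coding
convention.  Per-risk-genotype effects default to 6.55 (TC), −1.12
(HDL-c) and 4.20 (TG) mg/dl, cycling through recessive, dominant and
heterozygote-advantage patterns.

Residual SDs are not free parameters: they are calibrated analytically so
the marginal lipid SDs hit their targets (TC 38, HDL-c 12.9, TG 56 mg/dl).
Because covariates are independent by construction, the explained variance
has the closed form Σ genotype-triplet variances + Σ β²·Var(x), which the
truth record stores together with the implied population R² per lipid
(including derived LDL-c).

Two distributional choices keep that bookkeeping exact: covariates whose
positivity floor sits well inside the normal range (VFAT, METs) are drawn
from a moment-matched lognormal instead of a truncated normal, and lipid
floors are placed ≥ 3 SD below the means (the TG floor of 20 mg/dl trims
≈1% of draws; the empirical-vs-analytic R² agreement stays within ~0.01).

What the generator does **not** emulate: covariance among lifestyle
covariates and between adiposity and diet (independence by default, with
an optional Gaussian-copula correlation for BMI/TFAT/VFAT), linkage
disequilibrium between SNPs, genotyping error or missingness patterns,
non-normal lipid distributions, and gene–environment interactions unless
explicitly scripted.  Tests that pass on these cohorts therefore validate
the statistical machinery, not robustness to those real-data features.

## Hardy–Weinberg and AMOVA

Per SNP both a 1-df χ² goodness-of-fit test and the conditional exact test
are reported: the exact p sums the probabilities of all heterozygote
counts (given the allele counts) no more probable than the observed one.
Monomorphic SNPs are trivially in HWE (p = 1, flagged).  The two p-values
decide identically at α = 0.05 in ≈99.6% of well-powered draws, but their
raw values can differ substantially near perfect HWE proportions, where
the discrete exact p saturates at 1 — which is why the package reports
both rather than presenting one as an approximation of the other.

The homogeneity check is a one-level AMOVA: distance between subjects is
the squared difference in alternate-allele counts summed over SNPs; sums
of squares partition within/among groups; variance components follow the
standard expected mean squares; Φ is the among-group share; significance
comes from permuting group labels with an add-one correction (p is never
0, and with 99 permutations the test is exact at the 5% level under
exchangeability).  The grouping factor is a required input — for a plain
homogeneity check `homogeneity_check` uses repeated random halves, since
no natural grouping exists in a single-site cohort.  Missing genotypes
are mean-imputed per SNP for the distance computation only.

## GRS construction

Stage semantics (defaults in `GrsConfig`):

* prescreen keeps ANOVA p ≤ 0.25 (the discard rule is p > 0.25);
* t-selection keeps p < 0.10 *and* a mean difference in the adverse
  direction (higher for TC/LDL-c/TG, lower for HDL-c);
* the prevalence filter excludes codings where either category holds
  strictly less than 10% of subjects.

The coding step makes the grouping rule deterministic: Levene's test
(α = 0.05, median-centred) chooses Bonferroni-adjusted pooled-t pairwise
comparisons under homogeneous variances, otherwise Welch pairwise
comparisons with a Šidák-type multiplicity adjustment (the independence
member of the studentized-maximum-modulus family Dunnett's T3 belongs to;
exact SMM quantiles are not exposed by scipy/statsmodels and the
difference is third-decimal at m = 3 comparisons).  The genotype with the
most adverse mean anchors the risk category; genotypes not significantly
different from the anchor (p ≥ 0.05) join it; the remainder are nonrisk.
An alternative anchored-on-the-favourable-side grouping is available by
config.  If nothing separates from the anchor the SNP cannot be coded and
is dropped with reason `no_separable_categories`.  Genotype groups below
2 subjects are merged into the group with the nearest mean before testing
and inherit its label.

Missing genotypes: the default GRS is per-lipid complete-case (a subject
missing any contributing genotype gets NaN for that lipid's score and
drops from that lipid's models); scoring over observed SNPs is available.

Power note for the coding step: the binding comparison is against the
anchor genotype, whose group can be as small as n·q².  At n ≈ 300 the
Bonferroni-adjusted pairwise test needs a noncentrality near 4 for ~95%
per-SNP power — effects of ~0.75 residual SD at MAF ≥ 0.35.  The recovery
studies in the test suite are sized accordingly.

## Model selection and internal validation

Candidates per lipid: age, sex (female = 0 / male = 1), BMI, TFAT, VFAT,
METs, energy per 100 kcal, carbohydrate/protein/fat %E, cholesterol
intake (mg), smoking, drinking, and the lipid's own GRS.  Models are
complete-case; the fitted n is reported.

Information criteria use the Gaussian log-likelihood with
k = (#coefficients incl. intercept) + 1 for the error variance;
AICC = AIC + 2k(k+1)/(n−k−1).  The convention is stated because criterion
constants differ across software; all comparisons inside the package use
the same convention, where only relative values matter.

* **BSRP** enumerates all subsets (≤ 20 candidates).  Within a subset
  size every criterion is monotone in RSS, so only per-size RSS argmins
  are scored; the per-size minimisation runs as one batched linear solve
  over centred/scaled Gram submatrices (centring/scaling leaves RSS
  unchanged and keeps the systems well conditioned whatever the covariate
  units).  Ties break toward fewer predictors, then lexicographically.
* **LARS** computes the path on standardised predictors and picks the
  path support minimising Mallows' Cp (OLS refit per support;
  σ̂² from the full model); k-fold CV is a config alternative.
* **BSM** runs bidirectional p-value stepwise (enter 0.05 / remove 0.10,
  partial-F tests from the same Gram machinery) on each of B bootstrap
  resamples (default 200 standalone, 100 when nested inside optimism
  correction); predictors with inclusion frequency ≥ 0.60 are refit by
  OLS on the full data.

Optimism correction follows the resampling-revalidation scheme: for each
of B resamples (default 500; B = 50–100 in the test suite for runtime)
the *entire* selection is rerun, the selected model is fit on the
resample, and optimism_b = metric(fit on resample) − metric(same
coefficients applied to the original data), for metric ∈ {R², adjusted
R²}.  Corrected = apparent − mean optimism, a bookkeeping identity held
bit-exactly.  Rank-deficient resamples are redrawn and counted.  The
winner per lipid is the largest optimism-corrected adjusted R², ties to
the smaller model.

Two properties of the corrected estimate worth knowing: (i) under
aggressive selection on pure noise it overshoots below zero (models
selected on a resample predict the original data worse than its mean), so
it is a conservative, not merely debiased, estimate; (ii) its sampling
variability is that of R̂² itself — SD ≈ 0.04 at n ≈ 300 and R² ≈ 0.25 —
so replicate-level agreement with a population R² cannot be expected to
beat that floor, whatever the method.

PC² is computed as t²/(t²+df_resid), identical (to 1e−10 in tests) to the
squared correlation of the double-residualised response and predictor.
Interaction scans fit `lipid ~ GRS + L + GRS×L` per lifestyle variable
and report the product-term p; constant variables are skipped and logged.

## Validation problem sizes

The test suite exercises: closed-form genotype frequencies at n = 40 000;
truth-R² agreement on a 40 000-subject cohort; type-I calibration with
2000 (t-selection), 1000 (interaction scan) and 500 (AMOVA, 99
permutations each) replicates; and 100-replicate recovery studies at
n = 304 on 30-SNP panels with 6 causal SNPs per lipid.  These sizes keep
every check on a single CPU in minutes while leaving Monte-Carlo error
well inside the asserted tolerances (3 SE bands for calibration rates).

## Known limitations

* The coding rule is one deterministic reading of "group genotypes with
  similar effects"; anchoring on the favourable side instead changes
  codings for some SNPs (both are exposed, adverse anchoring is the
  default).
* Dunnett's T3 uses the Šidák/independence approximation to the SMM
  distribution (see above).
* AMOVA is single-level; hierarchical designs and LD-aware distances are
  out of scope.
* Corrected adjusted R² is conservative by construction; see the optimism
  notes above before comparing it to a known generating value.
* The generator's independence assumptions understate the collinearity of
  real adiposity/diet data, which makes selection on synthetic cohorts
  easier than on real ones.
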