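# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices, and the limits of what the test suite
demonstrates.

## The twin design

Monozygotic (MZ) co-twins share all segregating alleles, dizygotic (DZ)
co-twins on average half (a quarter for dominance deviations), and twins
reared together share their early environment regardless of zygosity.
Comparing within-pair resemblance across zygosity therefore separates
additive genetic (A), shared environmental (C) or dominance (D), and
unique environmental (E) variance.  All models here assume multivariate
normality of the phenotypes within a pair, random mating, no
sibling interaction, and equal shared environments across zygosity; the
saturated model (below) tests the equal-means/equal-variances part of
these assumptions on any given dataset.

## Data model

A cohort is one row per individual (person id, pair id, zygosity, sex,
age, BMI in kg/m², walkability in index units, four covariates).  CSV
dialect: comma-separated, UTF-8, header row, empty string = missing.
Within a pair, twin order is canonicalized by sorting on person id; every
likelihood is invariant to this ordering (tested).  Individuals missing a
phenotype stay in the cohort and are filtered per analysis, so one cohort
object serves all stages.  Covariates (never phenotypes) are imputed by
the column median; for 0/1 covariates the median is rounded so the filled
value is again a valid code.  Binary codings are fixed as employed=1,
bachelor-or-above=1, living-with-partner=1, female=1 so that regression
signs are reproducible.  Raw BMI must be positive at ingestion; analyses
may later store residualized (mean-zero) values in the same column.

## Regression layer

Individual-level association uses OLS point estimates with pair-clustered
sandwich standard errors and the small-sample factor
G/(G−1)·(n−1)/(n−k); this is the asymptotic equivalent of fitting the
model in an SEM framework with a robust (sandwich) estimator, in closed
form.  95% intervals use the normal quantile 1.96, matching large-sample
SEM practice.  The MZ co-twin-control model regresses within-pair BMI
differences on within-pair walkability differences with classical OLS
errors (one observation per pair); continuous covariates are differenced,
binary covariates enter as signed discordance codes (−1/0/+1), sex enters
at pair level (well defined for MZ pairs), and age is excluded because
co-twins share it.  The signed discordance choice preserves the
direction of a discordant covariate; an unsigned code would discard it.
Sex-stratified individual-level fits are available
(`fit_individual_stratified`); stratification splits opposite-sex DZ
pairs across strata, which the pair-clustered errors handle naturally.

## Univariate twin model

Parameterization is in paths (a, c-or-d, e), unconstrained in the
optimizer; variance components are their squares, so components are
implicitly non-negative and reported paths are canonically non-negative
(the sign is not identified).  The FIML likelihood sums bivariate-normal
terms for complete pairs (model-implied covariance per zygosity) and
univariate terms for singletons, with a single mean across twins and
zygosities; phenotypes are residualized on age and sex beforehand.

- **ICC**: ML correlation of the bivariate normal constrained to equal
  means/variances across twin order; CI by the Fisher-z transform,
  atanh(r) ± 1.96/√(n − 3/2).  An ANOVA-based ICC would differ slightly
  in small samples.
- **Base-model rule**: ADE if ICC_MZ > 2·ICC_DZ (strict), else ACE; DE
  models are excluded as biologically implausible.  Nested AE/CE/E models
  are compared by AIC = −2 lnL + 2k (k = paths + mean) and by LRT against
  the base model with df equal to the parameter difference.
- **Optimization**: BFGS from moment (Falconer) starting values plus 5
  jittered restarts, gradient tolerance 1e-8.  Non-convergence from every
  start raises; an E path estimated at its lower bound sets a warning
  flag (the likelihood degenerates as e→0).
- **CIs for standardized components**: profile likelihood at the
  χ²(1)=3.84 cutoff, searched by bracketing on the component share with
  the remaining parameters re-optimized (Nelder-Mead on mean, log total
  variance, and a logit split of the remaining share).  This reproduces
  the asymmetric intervals characteristic of variance components near
  their bounds.  If bracketing fails the fit falls back to delta-method
  intervals and says so in `ci_method`.
- **Saturated model**: per (zygosity × twin-order) means and variances
  plus a per-zygosity correlation (10 free parameters, complete pairs).
  Constraint sets (equal means/variances by order/zygosity) are fitted by
  ML and tested by LRT with df equal to the reduction in free
  parameters.

## Moderation model

The bivariate Cholesky moderation model treats the twin's own observed
residualized moderator value as a definition variable: each pair
contributes a 4-variate normal term over (M1, T1, M2, T2) whose
covariance is built from that pair's moderator values.  The moderator's
own ACE structure simultaneously captures gene–environment correlation;
the trait's loadings on the moderator's A/E common factors (and its own
unique factors) are linear in the moderator with slopes β.  Means of M
and T are constant: the M–T association is carried entirely by the
shared latent paths, and a direct mean regression of T on M would
double-count it (left as a deliberate non-feature; moderation of means
is outside this model family).  Complete pairs only: handling a missing
co-twin's definition variable has no canonical answer, and exclusion is
the conservative, testable choice (excluded pairs are counted).

An optional mean-moderation switch (`mean_moderation=True`) adds a linear
effect γ of the moderator on the trait mean.  It is off by default
because γ and the shared covariance paths are only jointly identified:
the likelihood pins down the total moderator→trait slope
γ + (a_M a_C + c_M c_C + e_M e_C)/Var(M), while the split between the
mean path and the covariance paths is weakly informed even at several
thousand pairs (tested — the identified total slope is recovered; the
split is not).  With the switch off, the phenotypic association is
carried entirely by the Cholesky covariance paths, which is also what
the variance decomposition interprets.

Variants: `no_shared_C` (the trait carries no shared-C path — appropriate
when the trait is AE, as BMI is) and `full` (adds c_C and β_cC).
`variant="auto"` fits the nested variant first, starts the full variant
from that optimum so the comparison is internally consistent, reports
the 2-df LRT, and keeps the nested model when its AIC improves on the
full one by more than 2.

**Optimization.**  The negative log-likelihood has an exact analytic
gradient (0.5·tr[(Σ⁻¹ − u uᵀ)∂Σ] terms with u = Σ⁻¹(x−μ), batched over
pairs), verified against central differences to 1e-6.  The surface is
genuinely multimodal: a small β with a large baseline path can mimic a
large β of opposite curvature, producing local optima separated in the β
directions.  The default strategy is therefore (1) fit the β-free
bivariate Cholesky from moment starts, (2) L-BFGS from that optimum, and
(3) restarts whose β components are jittered on their natural scale
0.5·sd(T)/sd(M) (at least six in `thorough` mode, the default), taking
the best converged optimum.  `thorough=False` (used in large replicate
studies) skips the extra restarts; under a no-moderation truth the
surface is unimodal in practice and the fast path is calibrated (tested).

**Variance profile.**  Var_A(m) = (a_C+β_aC m)² + (a_U+β_aU m)², likewise
Var_E(m); shares divide by their total (plus the C term in the full
variant).  A/E intersections are the sign changes of Var_A − Var_E on a
fine grid, polished by bisection to 1e-6.  Two crossings with A dominant
between them is the qualitative gene–environment-interaction signature
the moderation layer is designed to exhibit.

## Synthetic-data generators

Latents are standard normal and phenotypes Gaussian — deliberately the
same family the FIML fits assume, so recovery tests probe the estimators,
not distributional robustness.  Defaults are the study conditions:

- 477 MZ + 734 DZ complete pairs (1211 pairs, 4312 individuals when the
  regression generator's 2156 pairs are used);
- walkability mean 43.4, SD 12.0, variance split A/C/E = 0.22/0.22/0.56;
- BMI mean 26.5, SD ≈ 5.1;
- regression truth: slope −0.04 kg/m² per index unit (minimal model) or
  −0.02 conditional on covariates constructed to confound (binary
  covariates are thresholded Gaussian latents correlated with
  walkability; prevalences 0.89/0.62/0.72 as observed);
- BMI residual within-pair correlation 0.5 and walkability within-pair
  correlation 0.4 — familial clustering consistent with the observed twin
  correlations;
- moderation defaults: moderator paths from the walkability
  decomposition; trait AE with variance ≈26 (kg/m²)² and an additive
  share of ≈0.65 at the moderator's centre; shared paths a_C=−0.6,
  e_C=−0.25 chosen to reproduce the observed walkability–BMI covariance
  (phenotypic r ≈ −0.09); betas β_aU=−0.05, β_eU=0.4 (with β_eC=0.05)
  chosen once so that unique-environment variance overtakes genetic
  variance at both moderator extremes, with crossings near m≈+3 and
  m≈−20 on the residualized scale — the qualitative structure the
  moderation layer is meant to detect.

Singletons arise by random deletion (missing completely at random, under
which FIML is valid).  Moderation operates on the centered moderator; the
fitting side residualizes on age and sex first, which matches.

What the generators do *not* emulate: non-Gaussian BMI (real BMI is
right-skewed), assortative mating, selective attrition, measurement error
in self-reported BMI, spatial autocorrelation of walkability, or
opposite-sex-specific DZ structure (opposite-sex DZ pairs are treated
like same-sex DZ pairs).  Passing recovery tests therefore show the
estimators are correct and calibrated under the model's own assumptions,
not that those assumptions hold in registry data.

## Problem sizes in the test suite

Replicate studies run at the sizes that make their statistics meaningful
while keeping the suite brisk: 100 replicates at full cohort scale for
the A/C/E and slope recoveries, 200 replicates for ICC recovery and for
the null calibrations (the moderation-LRT calibration runs at 120+180
pairs — the χ²(4) null holds at any size — and the saturated-model
calibration at 100+150 pairs), and 10 replicates of 2000+2000 pairs for
the Falconer-vs-FIML agreement check.

## Known limitations

- Profile CIs are computed per component, not jointly; simultaneous
  coverage is below 95% by construction.
- The moderation model's likelihood conditions on the observed moderator
  through the definition variable while also modelling the moderator's
  marginal structure; this is the field's standard hybrid, and its
  finite-sample β estimates carry the usual small attenuation when
  moderation is strong.
- No sex-limitation, liability-threshold, or mean-moderation variants.
- The pipeline's moderation stage assumes both phenotypes can be
  residualized on age and sex; other covariate sets require calling the
  library directly.
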