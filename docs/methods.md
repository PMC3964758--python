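# Methods

## The phenotype score

The unit of analysis is weekly energy expenditure on regular leisure-time
exercise, in MET hours/week: for each reported activity, the MET value
(multiple of resting expenditure, ≈ 1 kcal/kg/h) times weekly frequency
times session duration in hours, summed over activities. Inclusion rules
operationalize "regular leisure": an activity counts only if practiced at
least 3 months per year and for at least half a year, and transportation,
gardening, house cleaning and compulsory school PE are excluded by the
`leisure_flag`. Scores above 120 MET h/week are truncated to 120.

MET values come from age-appropriate compendia: a youth table below age 18
and an adult table from 18. The shipped lookup (`data/met_table.csv`) is a
small curated table of ~30 common sports with separate youth and adult
columns; it is deliberately minimal — users with full compendium licences can
substitute any CSV with `activity, youth_met, adult_met` columns. Strata are
assigned strictly by age at survey (child < 13, adolescent 13–17, adult
≥ 18).

Longitudinal surveys are merged to one score per individual with adult-first
precedence: drop surveys taken past age 50 and surveys where the respondent
was injured, then take the most recent adult record, falling back to the most
recent adolescent and then child record. "Most recent" is wave order; ties
break by higher age at survey, then lexical wave id (the survey waves are
batched, so an explicit tie rule is needed even though ties are rare).

## Genotype coding and QC

SNPs are coded 0/1/2 as copies of a designated counted allele; the counted
allele for each panel variant follows the published genotype-column order.
Multi-allelic VNTRs are collapsed to copies of one focal repeat (DRD4
7-repeat, DRD5 148-bp allele, DAT1 480-bp allele), which also makes the
Hardy-Weinberg test well-defined for them (focal vs pooled-rest biallelic).

The default HWE test is the 1-df Pearson chi-square of observed vs expected
genotype counts at the sample allele frequency, without continuity
correction — this reproduces published table values from their printed
genotype-group counts at 2 dp. A standard exact conditional test
(`method="exact"`) is provided; for the panel's sample sizes the two agree
to ~0.01. Monomorphic samples return p = 1 by convention.

Mendelian checks operate on hard calls: a trio errs when the child's code
lies outside the interval implied by what each parent can transmit, a duo
when a homozygous parent's obligatory transmission is contradicted. The rate
denominator counts parent-offspring transmissions (2 per trio, 1 per duo).
Dosage vectors (expected allele counts from imputation, in [0, 2]) are
accepted for allele-frequency and association work but are refused by HWE
and Mendelian checks rather than silently rounded.

QC verdicts are pure functions of (metrics, thresholds) with defaults
HWE p > 1e-5, MAF > .01, Mendelian error rate < .02, call rate > .95,
reference-frequency difference < .20, cross-platform concordance > .95.
Metrics whose inputs are absent (no pedigree, no reference frequency, no
duplicate platform) are skipped, not failed.

The polygenic risk score sums, over variants, the copies of the allele
hypothesized to *increase* dopamine signalling. The shipped mapping
(`data/effect_alleles.yaml`) encodes the published hypothesis table as
printed, including its counter-intuitive rs6275 row (G paired with decreased
dopamine level via increased D2 autoreceptor expression); for the DRD5 and
DAT1 repeats, whose focal allele lowers dopamine signalling, the effect
allele is the *absence* of the focal repeat. Scoring is complete-case: an
individual missing any included variant gets a missing score.

## The kinship mixed model

The association model is y ~ N(Xβ, σ²ₐA + σ²ₑI) with maximum-likelihood
estimation. X contains an intercept, sex (0 = male, 1 = female), age
z-scored on the analysis sample, their interaction, and the variant code(s)
or risk score; users can append ancestry/batch/platform covariates as plain
columns. A is the additive genetic relationship matrix from the pedigree:
twice the kinship coefficient, computed by the recursive tabular method,
with MZ co-twins treated as genetically identical (their rows duplicate the
representative twin's, mutual entry 1). A is block-diagonal by family and
positive semidefinite (MZ blocks are singular, which is harmless since
σ²ₑ > 0).

Fitting profiles the likelihood over the variance ratio λ = σ²ₐ/σ²ₑ. Each
family block of A is eigendecomposed once (blocks repeated across families
are decomposed once and reused); rotating y and X by the block eigenvectors
makes the covariance diagonal with weights 1 + λd, so each profile
evaluation costs O(N) after the rotation. λ is maximized by bounded Brent
search on log λ over [1e-8, 1e4] (xatol 1e-8), and the boundary σ²ₐ = 0 is
evaluated explicitly and preferred when not distinguishably worse — the
ratio is unidentified when A = I, and the boundary convention makes the
identity-A fit collapse to OLS exactly. β and σ²ₑ then have closed GLS/ML
forms, with fixed-effect covariance σ̂²ₑ(XᵀW⁻¹X)⁻¹. ML (not REML) is the
default and what all reported numbers use; with ≥ 2,000 individuals and ≤ 5
fixed effects the REML correction is negligible for the tests performed.

Single coefficients are tested by the two-sided Wald statistic (β̂/se)²
against χ²₁; nested models by the likelihood ratio 2Δℓ against χ² with df =
number of added terms, computed on the identical complete-case sample
(enforced, since per-variant missingness changes the sample). The
Bonferroni-corrected per-test α for the 11-variant panel is .05/11 ≈ .0045.

Whether the original SPSS analysis parameterized the genetic random effect
exactly this way is not recoverable from the published description; the
relationship-matrix covariance σ²ₐA is the canonical quantitative-genetic
interpretation and is what this package defines. The alternative — a shared
family intercept — is strictly coarser (it equals σ²ₐA only when all family
members are first-degree relatives and MZ status is ignored).

## The synthetic cohort generator

The generator emulates a twin-register sample, not any particular dataset.
Families are drawn i.i.d. from a template mixture, by default 40% MZ twin
pairs, 40% DZ pairs, 15% DZ pair + one extra sibling, 5% single
participants. The true register composition is unpublished; this default is
twin-pair-dominated (mean family size 2.10) and configurable. Twin parents
are generated as founder allele sources flagged out of the analysis sample.
Sexes are drawn with P(female) = .62 (MZ pairs same-sex); ages uniform on
18–50. Sex and age exist so the full fixed-effect model can be exercised,
but carry no phenotype effect — the power analysis deliberately omits them,
making its estimates conservative.

Genotypes are gene-dropped: founders get two i.i.d. Bernoulli(MAF) alleles
(Hardy-Weinberg), children one uniformly chosen allele from each parent, MZ
co-twins a copy of their representative's genotype. Gene-dropped data are
Mendelian-consistent by construction, and the test suite asserts this on
every simulated dataset.

The phenotype is a latent Gaussian: y* = β(g − 2p) + a + e with
var(βg) = R² (using var(g) = 2p(1−p)), a ~ N(0, h²·A) the additive
polygenic deviate, e independent; y* is affine-mapped to mean 13 and SD 18
MET h/week, then floored at 0 and capped at 120. Defaults: h² = 0.55 (the
midpoint of adult twin-study heritability estimates of 50–60%), mean/SD in
the ballpark of published adult genotype-group means. The floor censors
~24% of the mass at 0, giving the characteristic right-skewed,
zero-inflated shape; the cap is nearly inert at these moments. One master
seed drives everything; replicate streams are spawned via numpy's
SeedSequence so each replicate is independently reproducible.

What the generator does *not* emulate: the real phenotype's stronger zero
inflation (in register data roughly half of adults report no regular
exercise, where the latent mean-13/SD-18 model censors only a quarter),
age/sex phenotype effects, assortative mating, shared-environment variance,
genotype missingness patterns, and linkage disequilibrium between variants
(each variant is dropped independently). Passing tests therefore demonstrate
the statistical machinery is correct under the stated generative model, not
that the model reproduces every property of register data.

## Power analysis

One power run fixes the pedigree (composition is a nuisance parameter),
then per replicate regenerates genotypes and phenotype, fits the mixed model
with intercept + variant only, and records the variant's Wald p-value.
Power is the rejection fraction at α = .05/11 with a 95%
normal-approximation binomial CI (Wilson available); replicates whose fit
fails are excluded and counted, and a run with > 5% failures is flagged
invalid. The four standard cells anchor the published sample sizes:
(N = 2,152, MAF .43, R² = .005), (3,140, .21, .01), (7,734, .30, .0025),
(8,756, .19, .005), at 1000 replicates each. At these settings a full
4-cell table takes ~20 s on one CPU thanks to the per-family spectral
profiling.

**Sensitivity of the power values.** The original simulation's recipe
(phenotype family, heritability, family mixture) was not published. Under
this package's defaults the engine gives rejection rates of roughly
.50/.98/.83/1.00 for the four cells, systematically above the published
.36/.91/.69/.97 except at the largest sample. The engine itself is
well-calibrated — type-I error at α = .05/11 sits inside the binomial band,
the unrelated/untruncated limit matches the noncentral-χ² closed form, the
empirical variant R² and MZ/DZ correlations match their configured values —
so the gap traces to the generative assumptions, most plausibly the floor
censoring: matching the published *observed* moments (mean ≈ 13, SD ≈ 18
after censoring, with roughly half the sample at zero) would require a
latent mean near 2 and SD near 30, whose stronger attenuation of the
genotype-phenotype covariance lands power near the published values. The
package keeps the declared latent parameterization (configured mean/SD are
exact pre-truncation moments, a cleaner contract for a reusable generator)
and reports the discrepancy rather than tuning the distribution to match.

## Numerical conventions

- Variance-ratio search: bounded Brent on log λ, tolerance 1e-8; explicit
  boundary check at σ²ₐ = 0 with a relative tie tolerance of 1e-9.
- Rank deficiency is detected via Cholesky failure of XᵀW⁻¹X and raised,
  never silently pseudo-inverted.
- HWE on monomorphic samples: p = 1. MAF is folded to [0, 0.5] and invariant
  to which allele is counted.
- The LRT statistic is clipped at 0 (tolerance 1e-6 before erroring), and a
  full-vs-identical-null comparison returns df 0, p = 1.
- Binomial CIs are clipped to [0, 1].
- Age standardization uses the n−1 denominator and refuses constant ages.
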