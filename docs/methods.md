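# Methods

This note documents the statistical procedures implemented in `obesnp`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Study design

The package models a two-stage design common in genetic epidemiology of
obesity: (1) a cross-sectional survey of adults aged 20–80 with measured
BMI, demographic and lifestyle covariates; (2) a nested 1:1 matched
case-control sample in which every obesity case (WGOC cut-off, BMI ≥ 28
kg/m²) is paired with a normal-weight control (18.5 ≤ BMI < 24) of the
same sex within ± 3 years of age, genotyped at a small panel of biallelic
SNPs. BMI intervals are half-open with inclusive lower bounds, so
`classify_bmi` partitions (0, ∞) and is monotone.

Effect (risk) alleles are fixed per SNP as the minor allele in the
control group — C for rs17782313, A for rs12970134, A for rs1121980, G
for rs17817449 — i.e. the allele whose carriage raises the odds of
obesity. A subject missing the genotype at one SNP is excluded from that
SNP's analyses and from both risk scores (complete case), with the count
logged.

## Prevalence and standardization

Crude prevalence uses the full sample as denominator. Stratified
estimates keep zero-denominator strata (flagged with a NaN rate) rather
than dropping them. Direct standardization computes Σₐ wₐ pₐ / Σₐ wₐ over
sex × age-band strata with user-supplied external weights (e.g. a census
population); it is invariant to rescaling the weights, and a stratum with
no observations but positive weight is an error because its rate would be
undefined yet weighted. Age bands default to decades (20–29 … 60–80) and
are configurable.

All categorical comparisons use the asymptotic Pearson chi-square test
without continuity correction (matching the convention of the major
commercial statistics packages), df = (r−1)(c−1). p-values are rendered
as `<0.0001` below 10⁻⁴ in reports while full precision is kept in
machine-readable output.

## Matching

The matcher is deterministic: cases are processed in (sex, age, id)
order; each takes the unused eligible control with the smallest absolute
age difference, ties broken by lower control age then lexicographic id.
A pure greedy pass can strand a case whose only eligible controls were
consumed earlier even though a full assignment exists, so a second,
equally deterministic augmenting-path (Kuhn) step re-routes earlier
assignments whenever that lets an unmatched case be paired. The result
always attains the maximum possible number of pairs (verified against an
exhaustive assignment oracle on small instances); the total age gap is
near- but not provably minimal, which we accept in exchange for
reproducibility and a simple algorithm. Unmatched cases are returned,
never silently dropped. By default controls are restricted to the
normal-weight band; a flag admits underweight subjects for a plain
"BMI < 24" eligibility rule.

## SNP statistics

Hardy-Weinberg equilibrium is tested in the control group with the
asymptotic chi-square comparing observed genotype counts to n·(p², 2pq,
q²) at the estimated allele frequency, df = 1 (one frequency estimated).
An exact test is deliberately out of scope: at the sample sizes involved
(hundreds of controls, minor-allele frequencies ≈ 0.2) the asymptotic
test is accurate, and its p-value is verified to be uniform under the
null by simulation. Case-control comparisons are Pearson chi-square on
the 2×3 genotype and 2×2 allele tables; the allelic odds ratio is the
cross-product ratio, with the Haldane-Anscombe 0.5 correction applied
only when a cell is zero (the chi-square itself is never corrected).

Inheritance models code the effect-allele dosage g ∈ {0,1,2} as dominant
(0,1,1), recessive (0,0,1), additive (0,1,2), or codominant (two
indicators for het and hom-effect against hom-ref).

## Regression engines

Both engines are maximum-likelihood, fitted by full Newton-Raphson with
step-halving whenever a step would decrease the log-likelihood, so the
likelihood is non-decreasing across iterations. Convergence requires the
score norm below 10⁻⁸ within 50 iterations. The design matrix is checked
for full column rank up front (collinear columns are named via QR), and a
coefficient exceeding 15 on the log-odds scale before convergence raises
a separation error rather than returning a meaningless estimate.

The unconditional model optionally replaces the model-based covariance
with a cluster-robust sandwich estimator (Stata-style small-sample factor
G/(G−1)·(n−1)/(n−k)) keyed on a cluster-id column. This is the package's
pragmatic account of a clustered sampling design — point estimates are
unaffected and only the variance is adjusted; full design-based survey
weighting is out of scope.

The 1:1 conditional logistic likelihood Π exp(βᵀx_case) /
(exp(βᵀx_case) + exp(βᵀx_control)) is maximized as an intercept-free
Bernoulli likelihood on per-pair case-minus-control differences — the
classical reduction for pair-matched data. Pairs concordant on every
covariate contribute no information and are dropped with a logged count;
with a single binary exposure the estimator reduces to the McNemar closed
form log(b/c), which the tests assert. Wald (symmetric on the log scale)
confidence intervals are used throughout, matching standard reporting;
reference levels for categorical covariates are female sex, age 20–29,
urban residence, low income, primary-or-below education, never
smoke/drink, and light activity levels. Adjusted matched-sample models
condition on residence, income, education, smoking, drinking,
occupational physical activity, and leisure-time exercise (sex and age
are absorbed by the matching).

## Risk scores

GRS is the unweighted sum of effect-allele counts (0–8 over four SNPs).
wGRS multiplies each count by a per-SNP log-OR weight; weights default to
the panel's own additive-model conditional-logistic estimates from the
same matched sample (floored at a small positive value so a SNP whose
estimated OR dips below 1 keeps a valid weight), and external published
weights may be supplied instead — whether internal or external weights
are preferable is surfaced as configuration rather than guessed. Tertile
cutpoints are the empirical 1/3 and 2/3 quantiles of the pooled
case + control scores; a score tied with a cutpoint goes to the lower
group, and tertile assignment is invariant to strictly monotone
transformations of the score. Association is estimated with T2 and T3
indicators against T1 in the adjusted conditional model.

## Gene-environment interaction

Genotypes enter under dominant coding; behavioural exposures are
dichotomized as current smoking, current drinking, heavy occupational
physical activity, and heavy leisure-time exercise (config-overridable —
these groupings are an assumption, not uniquely determined by the
reference tables). The multiplicative test is the Wald test of the
product-term coefficient. Additive interaction uses the joint
(three-indicator) parameterization — G+E−, G−E+, G+E+ against G−E− —
because its delta-method gradients are simple:

* RERI = OR11 − OR10 − OR01 + 1, gradient (−OR10, −OR01, OR11);
* AP = RERI/OR11 by the quotient rule;
* SI on the log scale, ∇ln SI = (−OR10/d, −OR01/d, OR11/(OR11 − 1)) with
  d = OR10 + OR01 − 2; the CI of ln SI is exponentiated.

When d ≤ 0 (or OR11 ≤ 1) SI is undefined and reported as such, with RERI
and AP still returned. An interaction is declared present only when the
RERI and AP intervals exclude 0 *and* the SI interval excludes 1. The
delta-method variances are first-order: they are accurate for the small
covariances of large-sample fits (verified within 2% of Monte-Carlo
propagation at fitted-scale covariances ≈ 5·10⁻³) but would be badly
biased for coefficient variances of order 1 — a known limitation of the
method, not of the implementation. The exposure's own parent covariate is
removed from the adjustment set of its interaction model, since the joint
coding already spans it and the design would otherwise be exactly
rank-deficient.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with defaults
calibrated to the reference survey:

* sex (P(male) = 0.4997) and every categorical covariate drawn
  independently from the survey's marginal proportions;
* integer age uniform within the drawn decade band;
* genotypes per SNP as Binomial(2, q) at the control-group effect-allele
  frequencies (q = 0.2351, 0.2022, 0.2273, 0.2147) — exact HWE in
  expectation;
* obesity drawn from a logistic model whose default coefficients are the
  survey's reported adjusted odds ratios: male 2.33, age 50–59 vs 20–29
  12.22, current smoking 0.44, heavy occupational activity 0.79, heavy
  leisure exercise 1.55, MC4R additive 1.45 and 1.42. Odds ratios the
  survey did not print were set once to plausible values — age 30–39,
  40–49, 60–80 at 3.0, 7.0, 11.0 (bracketing the printed 50–59 peak and
  the crude age gradient) and the two FTO SNPs at 1.10 and 1.05
  (reported non-significant) — with all remaining terms at 1.0. The
  intercept −4.13225 was calibrated by root-finding so the marginal
  obesity prevalence equals the survey's crude 19.47%;
* optional gene-environment product terms on dominant(g) × exposure;
* BMI drawn uniform within the band of the assigned class (only the
  class matters downstream); non-obese subjects split 4% / 54.2% / 41.8%
  among underweight/normal/overweight. The underweight fraction exists so
  the BMI < 18.5 sensitivity re-analysis has something to delete; it
  carries no risk association.

One `numpy` Generator seeded from a single integer drives every draw, so
output is byte-identical across runs at a fixed seed.

What the generator does **not** emulate: the joint (correlated)
distribution of covariates, the spatial/cluster structure of a real
multi-stage survey, genotyping error and missingness, linkage
disequilibrium between the SNPs (drawn independently), and any
BMI-covariate relationship beyond the binary obesity model. Passing tests
therefore demonstrate the correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulation-based checks use n = 10⁵ cross-sectional subjects and ~10³
matched pairs for parameter recovery (20 seeds), 200 seeds of n = 2,500
for interaction null calibration, and 10⁵ Monte-Carlo draws for the
delta-method check — sizes at which the asymptotics the methods rely on
are comfortably in force while the whole suite stays fast. Tolerances:
score norm 10⁻⁸ for both fitters; conditional-logistic agreement with a
brute-force grid oracle to 10⁻⁴; reference p-values asserted to the 4
decimals at which they are conventionally printed.

## Known limitations

* No exact (permutation/Fisher) tests; all inference is asymptotic.
* No Firth correction or exact conditional logistic for sparse strata.
* No survey-design weighting beyond the cluster sandwich.
* Matching minimizes pair count shortfall, not total age gap.
* wGRS default weights are estimated in-sample, which recycles the data;
  external weights are supported and preferable when available.
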