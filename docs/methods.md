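# Methods

## The score

`grstrata` implements a population-standardized multiplicative genetic risk
score (GRS) for SNP panels with externally estimated per-allele effects.
For a SNP with allelic odds ratio $OR$ and risk-allele frequency $p$ in the
reference population:

1. **Genotypic odds ratios.** Under a multiplicative (log-additive) model
   the genotypic ORs for 0, 1, 2 copies of the risk allele are
   $(1, OR, OR^2)$.
2. **Genotype frequencies.** Hardy–Weinberg equilibrium at frequency $p$
   gives $f = ((1-p)^2,\; 2p(1-p),\; p^2)$.
3. **Standardization.** The population-mean risk is
   $m = \sum_g OR_g f_g$; each genotype's risk *relative to the population
   average* is $OR_g / m$, so its population expectation is exactly 1.
4. **Aggregation.** A subject's GRS is the product of per-SNP relative
   risks. For independent SNPs the population-mean GRS is 1: a score of
   1.5 reads as "1.5× the average genetic risk".

Standardization deliberately uses the panel's stated reference frequencies,
not the observed cohort, so the score is cohort-independent and transfers
between datasets genotyped on the same panel. Genotype frequencies may
alternatively be supplied directly; HWE from the stated allele frequency is
the default. The product is accumulated in log space, so panels of hundreds
of SNPs cannot underflow.

**Missing genotypes** contribute a neutral factor of 1 (population-average
risk) by default — the standard convention for this score family — with the
SNP counted in `n_snps_missing`. A `drop_subject` policy is available for
sensitivity analysis. A subject with *every* panel genotype missing is
excluded with a warning under either policy.

**Allele bookkeeping.** When reading VCF, panel sites are matched by rsID
and then by chrom+pos; if the risk allele is the REF allele the ALT dosage
is complemented ($2 - d$). A risk allele matching neither REF nor ALT is a
hard error, and strand-ambiguous (A/T, C/G) panel SNPs trigger a warning at
read time: silent strand flipping is a well-known source of sign errors in
polygenic scores, so it is never attempted.

## The stratified interaction analysis

Genetic risk strata are the empirical tertiles of the GRS: values strictly
below the 1/3-quantile are *low*, values in $[q_{1/3}, q_{2/3})$
*intermediate*, values $\ge q_{2/3}$ *high*. Quantiles use linear
interpolation; ties share a stratum (a degenerate distribution collapses
into fewer strata with a warning). The right-closed lower boundary is a
documented convention — quantile conventions differ across software.

Two model families are fitted by unconditional logistic maximum likelihood
(`statsmodels`), with Wald 95% CIs and p-values:

* **Per-stratum BMI OR** — within each stratum, outcome on BMI plus the
  adjustment covariates; the exponentiated BMI coefficient is the adjusted
  per-unit-BMI (kg/m²) odds ratio.
* **Interaction model** — one pooled model with BMI, stratum dummies (low =
  reference), BMI × stratum product terms, and the covariates. The
  exponentiated product-term coefficient is the interaction OR: the ratio
  of per-unit-BMI odds ratios between that stratum and the low-GRS
  reference. In the saturated configuration (no extra covariates) it
  coheres exactly with the separate per-stratum fits, and the test suite
  asserts this identity numerically.

The default adjustment set is age, log-PSA, prostate volume, DRE finding
and family history — the covariates associated with biopsy outcome in this
study design. It is configurable; "conventional risk factors" is not a
fixed list across the literature. Raw p-values are reported without
multiplicity correction, matching how such interaction tests are usually
published.

**Secondary outcome.** For high-grade disease, cases are biopsy-confirmed
high-grade cancers and controls are everyone else, including negative
biopsies. This is one of several defensible contrasts; it is a package
decision, stated here because definitions vary.

**Baseline table.** Continuous variables are summarized as median (IQR) and
compared with the Kruskal–Wallis rank test; categorical variables as count
(%) with a chi-squared test (no continuity correction). Constant variables
get `p = NA` with a warning.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of a two-center Chinese prostate-biopsy cohort:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 1120 | typical cohort size for this design |
| genotypes | HWE at panel frequencies | binomial(2, p), independent SNPs |
| `bmi_mean`, `bmi_sd` | 24, 3 kg/m² (truncated at 15) | median BMI ≈ 24 typical of Chinese men |
| `age_mean`, `age_sd` | 67, 8 y (clipped 40–95) | biopsy-referral age range |
| `log_psa_mean`, `log_psa_sd` | 2.3, 0.9 | log-normal PSA centred near 10 ng/mL, the biopsy "gray zone" |
| `volume_mean`, `volume_sd` | 45, 18 mL (floor 10) | biopsy-population prostate volumes |
| prevalences | DRE 0.25, family history 0.03, smoking 0.45, drinking 0.30, hypertension 0.30, diabetes 0.12 | family history is rare in Chinese cohorts |
| `beta_bmi_by_stratum` | (0.0, 0.07, 0.155) | per-unit-BMI log-OR by stratum: null at low risk rising to OR ≈ 1.17 at high risk |
| `beta_covariates` | age 0.04, log-PSA 0.9, volume −0.03, DRE 1.1, family history 0.8 | directions and magnitudes typical of biopsy-outcome models |
| `baseline_logit` | −5.912 | calibrated once (bisection, n = 200,000) so the default case fraction is ≈ 0.434 |
| `high_grade_frac` | 0.35 | share of high-grade disease among cases |

The outcome is Bernoulli with logit
`baseline + beta_bmi[stratum]·BMI + Σ beta·covariate`. Crucially the
stratum here is the subject's **realized GRS tertile**, computed in-pipeline
with the same scorer and stratifier the estimator uses — not a latent
label — so recovery experiments cannot be flattered by an oracle
stratification the estimator never sees.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, PSA-driven biopsy selection (verification
bias), repeat-biopsy dynamics, or any BMI–PSA dependence. Passing recovery
and calibration tests therefore demonstrates that the estimator is correct
*under its own assumptions*; they say nothing about confounding or
selection in real biopsy cohorts.

The bundled 24-SNP panel (`data/synthetic_panel_24.csv`) is a synthetic
stand-in — ORs log-uniform in [1.05, 1.45], frequencies uniform in
[0.1, 0.9], unambiguous allele pairs, fixed generation seed — shaped like a
GWAS-derived prostate cancer panel. Its first 7 SNPs serve as the companion
subset panel, mirroring an overall / population-specific panel pair. It
carries no real association results.

## Monte-Carlo validation

`grstrata.validation` runs two end-to-end studies (simulate → score →
stratify → fit), with replicate seeds spawned from one master seed:

* **Type-I calibration**: identical BMI slopes in all strata; the
  high-vs-low interaction test should reject at the nominal 5% level.
  Default: 500 replicates of n = 2000.
* **Recovery**: the high stratum's slope exceeds the low stratum's by
  log 1.2, so the true interaction OR is 1.2; the mean estimate and the
  Wald CI coverage are reported. Default: 200 replicates of n = 5000.

These problem sizes keep each study under a minute on one core while the
Monte-Carlo error (binomial SE ≈ 1% on rates, ≈ 0.25% on the mean OR) stays
well inside the assertion bands.

## Numerical choices and edge cases

* GRS products in log space; genotype counts validated to {0, 1, 2, missing}.
* Logistic fits: Newton iterations (statsmodels default), `maxiter=200`;
  non-convergence, infinite standard errors or |coefficient| > 50 raise a
  fit error naming the stratum.
* A zero-variance adjustment covariate within a stratum is dropped with a
  warning, as is a binary adjustment covariate quasi-completely separated
  from the outcome (a zero cell in its 2×2 table; e.g. a 3%-prevalence
  family history in a stratum of ~350 where every carrier is a case — the
  MLE would diverge). BMI or stratum/product terms in that state raise
  instead: the estimand itself is then unidentifiable.
* A stratum with a single outcome class raises a degenerate-outcome error.
* `results.json` is serialized with sorted keys; identical inputs reproduce
  it byte-for-byte (fits are deterministic).

## Known limitations

* Interaction tests on tertile strata discard within-stratum GRS
  information; a continuous BMI × log-GRS term is often more powerful but
  less interpretable. The tertile parameterization is the primary contract
  here.
* Wald intervals degrade in small strata with rare covariates;
  profile-likelihood or Firth corrections are out of scope.
* The score assumes multiplicative independence of SNPs; panels with LD
  will overweight correlated loci.
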