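# grstrata

Population-standardized multiplicative genetic risk scores (GRS) for SNP
panels, and GRS-stratified analysis of how body-mass index predicts
prostate cancer at biopsy.

Growing evidence suggests that lifestyle predictors of prostate cancer act
differently depending on a man's inherited risk. `grstrata` is for
biostatisticians and genetic epidemiologists who want to (a) turn a panel
of GWAS-derived SNPs — each with an allelic odds ratio and a reference
allele frequency — into a per-subject genetic risk score whose population
mean is 1, and (b) test whether the BMI–outcome association is modified by
that genetic risk, using tertile strata and a product-term logistic model.
A synthetic-cohort generator with the same statistical structure makes the
whole pipeline testable end-to-end on a laptop, without any genotype
download.

## The score and the model

For each SNP with allelic OR and risk-allele frequency $p$: genotypic ORs
are $(1, OR, OR^2)$ (multiplicative model); genotype frequencies are
Hardy–Weinberg, $((1-p)^2, 2p(1-p), p^2)$; each genotype's risk relative to
the population mean $m=\sum_g OR_g f_g$ is $OR_g/m$; and the subject's GRS
is the product of relative risks across the panel. By construction
$E[\mathrm{GRS}] = 1$ in the reference population.

Subjects are stratified into low / intermediate / high genetic risk by GRS
tertiles. Per stratum, a logistic regression of biopsy outcome on BMI
(adjusted for age, log-PSA, prostate volume, DRE finding and family
history) yields the stratum's BMI odds ratio. A pooled model with
BMI × stratum product terms (low = reference) tests effect modification:
$\exp(\beta_{\mathrm{BMI}\times\mathrm{high}})$ is the ratio of per-unit-BMI
odds ratios between the high and low strata.

See `docs/methods.md` for the full model description, generator defaults,
and numerical choices.

## Worked example

Simulate a 1120-man biopsy cohort with the bundled synthetic 24-SNP panel,
then run the full analysis:

```bash
cat > sim.yaml <<EOF
seed: 11
n_subjects: 1120
EOF
grstrata simulate --config sim.yaml --out-dir data
cat > run.yaml <<EOF
panels:
  overall: data/panel.csv
genotypes: data/genotypes.csv
phenotypes: data/phenotypes.csv
out_dir: out
EOF
grstrata run --config run.yaml
```

which prints

```
panel overall:
  intermediate vs low: OR_interaction = 1.075, p = 0.258
  high vs low: OR_interaction = 1.204, p = 0.00578
report bundle in out
```

and writes `out/report.md`:

```
| GRS stratum | n | BMI OR (95% CI) | p |
|---|---|---|---|
| low | 373 | 0.943 (0.854-1.042) | 0.249 |
| intermediate | 373 | 1.042 (0.962-1.127) | 0.312 |
| high | 374 | 1.165 (1.065-1.273) | 0.000798 |

| Interaction (vs low) | OR (95% CI) | p |
|---|---|---|
| intermediate | 1.075 (0.948-1.219) | 0.258 |
| high | 1.204 (1.055-1.374) | 0.00578 |
```

Read: in this simulated cohort each BMI unit multiplies the odds of a
positive biopsy by 1.165 among men in the top GRS tertile, while BMI
carries no signal in the bottom tertile; the high-vs-low interaction OR of
1.204 (p = 0.006) says the BMI effect is significantly stronger at high
genetic risk — which is exactly the structure the generator was configured
with (per-unit log-odds slopes 0 / 0.07 / 0.155 by stratum). The bundle
also contains per-subject scores (`grs_overall.csv`: `subject_id, grs,
n_snps_used, n_snps_missing`), the stratified cohort table, a baseline
characteristics table (median/IQR + Kruskal–Wallis for continuous
variables, counts + chi-squared for categorical), and `results.json` with
every fit.

The same pipeline runs on real data: a panel CSV
(`rsid,chrom,pos,risk_allele,other_allele,allelic_or,risk_allele_freq`),
genotypes as VCF (matched by rsID, then chrom+pos; REF/ALT orientation
handled, strand flips never guessed) or as an rsID × subject count matrix,
and a phenotype CSV. `grstrata score` computes scores alone;
`grstrata analyze` accepts `--outcome high_grade` for the secondary
outcome and `--covariates` to change the adjustment set. Two panels in one
config (e.g. an overall panel and a population-specific subset) produce
parallel result sections.

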