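# sseqtl — two-stage discovery of sex-interacting cis-eQTLs

Genetic variants can regulate a transcript differently in males and
females.  Such *sex-interacting expression QTLs* (ss-eQTLs) — variants
whose genotype–expression slope differs between the sexes — are a route to
the molecular basis of sexually dimorphic traits, but they are hard to
detect: interaction effects need roughly four times the sample size of a
plain eQTL, and a handful of outlying expression values can fake one.

`sseqtl` is a library + command-line pipeline for mapping ss-eQTLs from
genotypes (VCF), a normalized expression matrix and sample metadata, for
cohorts of a few hundred samples.  It implements a two-stage procedure:

1. **Interaction screen.**  For every variant within ±1 Mb of a feature's
   anchor (gene TSS or miRNA locus; biallelic SNPs, MAF ≥ 1%), fit by OLS

       y = β0 + β1·SNP + β2·sex + β3·sex·SNP + β4·PC1 + β5·PC2 + β6·PC3 + e

   with dosage-coded genotypes (males 0/2 on the X), sex coded 0/1 and
   population PCs as covariates, and screen the two-sided β3 p-values with
   Benjamini–Hochberg FDR at q = 0.05.

2. **Sex-stratified robust validation.**  Refit each candidate separately
   in males and females with `y = β0 + β1·SNP + PCs + e` using a Huber
   M-estimator (IWLS, k = 1.345, MAD scale) so outliers are downweighted,
   test β1 with a robust Wald test, require every genotype-by-sex block to
   hold ≥ 5 samples with all genotypes present, apply a second BH screen to
   the pooled per-sex p-values, and call an ss-eQTL when either sex (or
   both) passes.

Around the core sit analytic power calculations (noncentral-F interaction
power, noncentral-t single-eQTL power over MAF × n), LD-based annotation of
calls against a trait-association catalog (r² > 0.8, catalog p < 0.05), and
a synthetic-data generator that reproduces the assumed generative model so
the whole pipeline is testable without controlled-access data.

## Worked example

The `analysis/` directory is a numbered walk-through.  Step 01 simulates a
study-style cohort (174 males, 160 females, 400 SNPs, 40 features, three
planted interactions) and writes it as VCF + TSVs; step 02 runs the full
two-stage scan on those files:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_two_stage_scan.py  --seed 0
```

which prints:

```
2488 cis pairs tested
stage 1: 2 of 2488 pairs pass BH at q=0.05 (equivalent p threshold 7.376e-08)
stage 2: 3 of 4 stratum tests pass BH (equivalent p threshold 8.119e-05)

final ss-eQTL calls (2):
variant_id feature_id chrom     pos  significant which_stratum
  var00000  feat00000     1   38293         True          both
  var00040  feat00001     1 1142221         True        female

planted-pair recovery:
  feat00000 x var00000 (beta3=1.0): CALLED
  feat00001 x var00040 (beta3=1.2): CALLED
  feat00002 x var00080 (beta3=0.35): not called
```

The two strong planted interactions are recovered — the second one in
females only, which is exactly what a sex-specific slope should look like —
while the weak one (β3 = 0.35) falls below stage-1 power at this sample
size, as the power analysis predicts: at n = 334 the interaction stage has
power 0.24 at Cohen's f = 0.1 and 0.81 at f = 0.2
(`analysis/03_power_analysis.py`).  Steps 04–05 annotate the calls against
a synthetic trait catalog via LD and measure the pipeline's operating
characteristics (false-call control under the null, planted-effect
recovery, Huber-vs-OLS robustness) by simulation.  All outputs land under
`results/`.

The same pipeline is available as a CLI for real data:

```bash
sseqtl run --config my_study.yaml --seed 1 --out-dir results/study
sseqtl power --n-total 334
```

where the YAML names the VCF, expression, feature-anchor and sample tables
(or a `simulate:` block), and the output directory receives the stage-1 and
stage-2 tables, the calls, both FDR screens with their equivalent p-value
thresholds, a filter-attrition log and a reproducible run manifest.

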