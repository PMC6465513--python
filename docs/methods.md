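# Methods

## Problem and model

A cis-eQTL is a statistical association between a nearby variant's genotype
and a transcript's expression.  A *sex-interacting* eQTL (ss-eQTL) is one
whose genotype–expression slope differs between males and females — a
nonzero sex-by-genotype interaction.  `sseqtl` implements a two-stage
discovery procedure for ss-eQTLs plus the supporting power, annotation and
simulation machinery.

**Stage 1 — interaction screen.**  For every cis variant–feature pair
(variant within ±1 Mb of the feature anchor, inclusive; the anchor is the
gene TSS or the miRNA locus) we fit by ordinary least squares

    y = β0 + β1·SNP + β2·sex + β3·sex·SNP + β4·PC1 + β5·PC2 + β6·PC3 + e

where `y` is normalized expression, `SNP` is the alternate-allele dosage
(0/1/2; on the X chromosome males are hemizygous and coded 0/2, females
0/1/2), `sex` is 0 for male and 1 for female, and the PCs are population-
stratification covariates supplied with the sample metadata (any number,
default three).  β3 is tested two-sided against t with n − p degrees of
freedom (p = number of fitted columns).  The Benjamini–Hochberg step-up
procedure at q = 0.05 screens the interaction p-values of one analysis
jointly; the screen reports its *equivalent p-value threshold* — the
largest rejected p.  Separate analyses (e.g. an mRNA run and a miRNA run)
are screened separately.

**Stage 2 — sex-stratified robust validation.**  Each stage-1 candidate is
refitted separately in males and in females with

    y = β0 + β1·SNP + β2·PC1 + β3·PC2 + β4·PC3 + e

using a Huber M-estimator solved by iteratively reweighted least squares,
and β1 is tested with a robust Wald statistic t = β̂1 / robust_se(β̂1)
against t(n − p).  Before fitting, a block QC filter requires every
genotype-by-sex cell to hold at least 5 samples with all genotypes present
(0/1/2 per sex on autosomes).  BH at q = 0.05 then runs over the pooled
male and female p-values of all candidates, and a candidate is called
significant when *either* stratum (or both) is rejected — the OR rule.

## Numerical choices

* **Stage-1 fitting.**  Single-pair fits use an SVD least-squares solve;
  the genome-wide scan uses a batched normal-equations path over pairs that
  share a complete sample set (per-pair 7×7 Gram matrices, batched solve),
  falling back to the single-pair path wherever dosages are missing or the
  fast path flags a problem.  A unit test pins the two paths to each other
  at 1e-9 relative, and both to an independent normal-equations oracle.
  Designs with condition number above 1e10 or rank deficiency are flagged
  `collinear`; fits with residual sum of squares below 1e-12 of the total
  sum of squares are flagged `degenerate_fit` (coefficients reported,
  inference withheld).  Pairs with a constant genotype, a single sex among
  complete cases, or fewer than p + 2 complete cases are skipped with
  reason codes and excluded from the BH test count m (logged).
* **Missing data.**  Missing dosages drop the sample for that pair only
  (complete-case per test); nothing is imputed.  Male heterozygous calls on
  the X are genotyping artifacts and are set missing with a logged count.
* **Huber IWLS.**  Tuning constant k = 1.345 (95% efficiency at the
  Gaussian) with the scale re-estimated each sweep as median(|r|)/0.6745
  (MAD, consistent for σ under normality); start at OLS; stop when
  max|Δβ| < 1e-8·(1 + max|β|) or after 50 sweeps.  The robust covariance is
  Huber's classical proposal, κ²·[s²·Σψ(u)²/(n−p)]/ψ̄′² · (X′X)⁻¹ with the
  small-sample correction κ = 1 + (p/n)·var(ψ′)/ψ̄′²; a full sandwich
  estimator is available via `cov="sandwich"`.  This matches the default
  M-estimation summaries of the standard R/statsmodels implementations
  (coefficients agree with `statsmodels.RLM(HuberT)` to ~1e-6, SEs to
  ~1e-5 relative, verified in tests).  A collapsing MAD (near-exact fit)
  sets a `degenerate_scale` flag; non-convergent or degenerate fits are
  treated as QC failures of that stratum, never errors.
* **BH ties and sentinels.**  Ties at the step-up boundary are rejected
  together; when nothing is rejected the equivalent threshold is reported
  as "none" (NaN), not 0.  NaN p-values (flagged fits) are excluded from m.
* **Window boundary.**  |pos − anchor| ≤ 1 000 000 is inclusive.  MAF
  (folded, ≥ 1% to keep a variant) is computed on the analysis samples
  after intersection; on the X, males contribute one allele and females
  two.  For minus-strand features the annotated end coordinate is the TSS;
  unknown strand falls back to the start with a warning.
* **X-chromosome QC.**  Hemizygous males can never show genotype 1, so on
  the X the block filter requires the realizable blocks only: male {0, 2}
  and female {0, 1, 2}, each ≥ 5.
* **Stage-2 BH pool.**  The default pools both sex-strata p-values of all
  candidates (two tests per candidate), which matches the OR-rule
  semantics; `pool="per-stratum"` screens males and females separately.

## Power calculations

`anova_interaction_power` treats the interaction screen as an omnibus
fixed-effects one-way ANOVA over the 6 sex-by-genotype cells: with Cohen's
effect size f and total n, power = P(F′ > F_crit) where F′ is noncentral F
with df1 = 5, df2 = n − 6 and λ = f²·n, and F_crit is the central-F 1−α
quantile.  At n = 334 and α = 0.05 this gives 0.2418 at f = 0.1 and 0.8108
at f = 0.2.  `eqtl_power` is the power of the two-sided level-α slope
t-test in a simple regression of expression on dosage: under HWE the
genotype variance is 2·maf·(1−maf), so the noncentrality is
slope·√(n·2·maf·(1−maf))/σ with n − 2 df; the noncentral-t form (not a
normal approximation) matters at per-sex n ≈ 160–176.  The closed form
plugs in the *expected* genotype variance, so it overshoots a direct
simulation of the test by ≈ 0.005 at maf 0.2, n 176 — tests assert
agreement to 0.01 absolute.

## LD annotation

LD between a called SNP and a catalog SNP is the squared Pearson
correlation of unphased dosages (composite LD) over shared complete cases —
the natural estimator when phase is unavailable.  A co-localization is
reported when r² > 0.8 (strict) and the catalog association has p < 0.05
(strict); only catalog SNPs within 1 Mb of the call are tested, and catalog
SNPs absent from the genotype matrix are skipped with a logged count.

## Synthetic-data generator

The generator emulates the data structure the pipeline assumes: 174 males
and 160 females by default, biallelic SNP dosages drawn Binomial(2, p)
under HWE (X: males Binomial(1, p) recoded 0/2) with p uniform over a
configurable MAF range, three standard-normal PCs (optionally given a
sex-correlated component to probe confounding), variant positions uniform
over a 10 Mb chromosome, and expression generated directly from the
stage-1 linear model with configurable coefficients per feature.  Each
feature has exactly one causal variant (possibly with all-zero
coefficients, i.e. null) and its anchor is placed uniformly within ±500 kb
of that variant, so the generative pair is always cis.  Noise is Gaussian
or a Tukey gross-error mixture (outliers ~ N(0, (scale·σ)²) with a given
probability, iid and independent of genotype and sex) to exercise the
robust stage.  One master seed derives an independent substream per
variant and per feature, so any subset regenerates bit-for-bit.

What the generator does *not* emulate: read-count noise and library
effects (expression is produced on the already-normalized scale the model
analyses), LD between variants (variants are independent; LD test fixtures
construct correlated pairs explicitly), realistic allele-frequency spectra,
and relatedness/population structure beyond the synthetic PCs.  Passing
tests therefore demonstrate the statistical machinery under its stated
assumptions, not performance on real sequencing data.

## Monte-Carlo experiment design

Problem sizes were chosen once as the package's validation design:

* **Null calibration** — 200 complete-null cohorts of 2 000 independent
  pairs at n = 334 in the test suite (the reporting script uses 100 × 1 000).
  Expected behaviour: the two-stage procedure yields zero calls in ≥ 95% of
  datasets (the stage-1 BH screen rejects anything at all in ≈ 5% of global-
  null datasets, and stage 2 must then also reject), and the pooled
  interaction p-values are uniform.
* **Recovery** — one planted β3 = 1.0 (σ = 1) among 499 null pairs,
  100 seeds.  The planted design (all MAFs in 0.25–0.45) was pilot-
  calibrated once so that the genotype-by-sex QC blocks are realizably
  filled (expected minimum block count ≈ 11 at n = 334) and stage-1 BH
  power is ≈ 0.9+; a wider MAF range (floor 0.15) loses ~8% of replicates
  to the block filter alone, which is the filter working as designed, not a
  power failure.
* **Robustness** — 500 single-stratum replicates at n = 160, MAF 0.3,
  slope 0.5, 5% outliers at 10σ.  The Huber fit roughly halves the mean
  absolute error of the genotype coefficient (MAE ratio ≈ 0.45–0.5).  Its
  *head-to-head win rate* against OLS is ≈ 0.78, not higher: under
  symmetric contamination both estimators are unbiased and strongly
  correlated (ρ ≈ 0.5) with an SD ratio of ≈ 2.2, which caps
  P(|RLM error| < |OLS error|) near 0.76–0.80 regardless of sample size —
  a property of the estimator pair, not of the implementation (the
  statsmodels RLM reference gives the same rate).  Win rates above 0.9
  would require far grosser (~30σ) contamination.

## Known limitations

* Stage-1 OLS p-values are exact only under Gaussian errors; the pipeline
  relies on stage 2 (not permutations) to control outlier-driven false
  positives, mirroring its parametric design.
* The stage-2 screen pools candidate strata; with very few candidates the
  BH pool is small and the equivalent threshold is coarse.
* `eqtl_power` ignores covariates and the two-stage selection effect; it
  describes a single pre-specified test.
* The annotation step tests only catalog SNPs present in the supplied
  genotype matrix; no external LD reference panel is consulted.
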