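# Methods and design notes

## Scope and model

The package analyses a candidate-SNP melanoma case-control panel for
sex differences in allelic effects. Every test is single-SNP: for
minor-allele dosage g ∈ {0, 1, 2} and a binary outcome y, the additive
logistic model `logit P(y=1|g) = β₀ + β·g` is fit by Newton/IRLS within
each sex stratum, with no covariates. The assumptions inherited from
that design are: independent samples (no relatedness or population
structure correction — the emulated study population showed no internal
genetic heterogeneity and controls were frequency-matched by age), a
log-additive allele effect, and outcome-dependent sampling that under a
logistic model leaves the slope interpretable as the per-allele odds
ratio (only the intercept absorbs the case-control ascertainment).

Sex-stratified estimates feed three chi-square statistics per
variant-outcome pair: per-sex 1-df Wald statistics, their 2-df sum, and
the 1-df heterogeneity statistic
`(β_F − β_M)² / (SE_F² + SE_M² − 2·cov)` with cov = 0 by default
because the strata are disjoint samples; the covariance argument exists
for correlated-estimate reanalyses. Wald (not likelihood-ratio)
inference is used throughout because the sex-differentiated statistics
are defined on beta/SE pairs, and because it makes the reanalysis path
from printed OR/CI tables exact: `β = ln OR`,
`SE = (ln CI_hi − ln CI_lo) / (2 × 1.959964)`.

A variant-outcome pair is flagged as a potential sex difference when a
sex-specific P < 0.05 in at least one sex and the heterogeneity
P < 0.05, both strict. The per-trait report threshold is 0.01
(Bonferroni over the six traits, 0.05/6); enrichment eligibility uses
0.05. All three levels are parameters.

## QC stage

* **Call-rate filter** (default ≥ 0.9 non-missing per variant): a
  dosage-level surrogate for instrument-level genotyping failure, which
  cannot be reproduced from dosage data.
* **Minor-allele orientation**: if the coded allele's pooled frequency
  exceeds 0.5, dosages are reflected (d → ploidy − d) and labels
  swapped; ties at exactly 0.5 keep the input orientation; the
  operation is idempotent. Alleles are taken as declared — no strand
  flipping is attempted, which is safe for a designed panel with known
  alleles but would not be for meta-analysis across platforms.
* **Exact HWE test**: the conditional test that, given the observed
  allele counts, weights heterozygote counts by
  `n!/(n_AA! n_Aa! n_aa!)·2^{n_Aa}` and sums the probabilities of all
  configurations no more probable than the observed one. Implemented in
  log-space with a 1+1e−12 relative tie tolerance; monomorphic variants
  return 1. Per-variant tests run within each sex and pooled ("in HWE"
  means p ≥ α/m, strict flagging below the threshold). With m = 363 and
  α = 0.05 the threshold is 1.3774 × 10⁻⁴; note that truncating (not
  rounding) the mantissa gives the conventionally quoted 1.37 × 10⁻⁴.
* **X chromosome**: males are hemizygous by default — X dosages in
  {0, 1}, one allele in allele tables, HWE in females only; regression
  uses the recorded dosage. `x_mode="autosomal"` disables the
  convention.

## Association fitting

Newton/IRLS on (intercept, slope), converged when the maximum absolute
score < 1e−8, at most 50 iterations; SE from the inverse observed
information. Separation is flagged, not penalised (no Firth
correction): a fit is `separated` when the slope escapes |β| > 15
during iteration or when the converged SE exceeds 100 (a flat
likelihood whose score vanishes while the maximum sits at infinity —
this second guard is what catches quasi-separation). `degenerate`
covers single-class outcomes, constant dosage and singular information.
Flagged fits carry no P value and are skipped downstream with a log
message. Complete-case filtering is applied per (variant, outcome)
pair; missing questionnaire answers are assumed uninformative.

## Enrichment stage

Significant associations are counted at the SNP-trait-pair level (a SNP
significant for two traits counts twice), split by direction
(protective OR < 1 vs risk OR > 1) and sex. Both the Pearson 1-df
chi-square without continuity correction and the two-sided Fisher exact
test are attached to every 2×2 table; the chi-square is the headline
column because it is the test the reference P values correspond to,
and the Fisher P is reported alongside for transparency. Degenerate
tables (a sex with no significant associations, or an empty direction
column) keep their counts and skip the tests that are undefined.

The packaged `data/enrichment_reference.tsv` is a **reconstruction**: the
per-trait integer counts were recovered from published percentages and
pooled totals (107 vs 75) and validated by reproducing all seven
published contingency P values; exact bar-top counts are not printed
anywhere in the source text. The packaged melanoma table
(`data/melanoma_reference.tsv`) carries printed, rounded OR/CI values;
heterogeneity P values recomputed from it agree with the published
sex-differentiated column only to rounding slack (e.g. rs2521667:
recomputed 1.8 × 10⁻³ vs published 7.85 × 10⁻⁴). One published entry,
rs2069398, has same-direction effects in both sexes (β_F ≈ −0.76,
β_M ≈ −0.51) for which the heterogeneity formula gives P ≈ 0.48; its
published sex-differentiated P of 0.0016 cannot be reproduced from the
printed values by this statistic at any rounding slack, so tests
document agreement only for the opposite-direction SNPs.

## Synthetic data generator

The generator's defaults are the emulated study's conditions: 316/283
female and 234/224 male cases/controls, 363 SNPs, MAF drawn uniformly
on [0.05, 0.5] (the panel was MAF-thresholded at 0.05; the uniform law
is configurable), genotypes as two independent allele draws (HWE), no
LD between SNPs, no population structure, 1% genotype missingness
(completely at random — a typical assay-scale loss; the emulated study
dropped whole failed SNPs rather than scattered calls), and 8 X-linked
SNPs (a small X fraction mirroring a panel where one candidate gene
region is X-linked) with hemizygous males. Trait prevalences default to
0.5 each; the source questionnaire's marginal frequencies are not
published, and balanced traits keep per-trait power comparable in
calibration studies.

Case/control status is rejection-sampled against the prospective
logistic liability with the intercept centred so the marginal
prevalence matches the target case fraction; draws continue until the
exact configured counts are hit (budget 10⁶ draws). Because the
logistic odds ratio is invariant to outcome-dependent sampling, planted
betas remain the estimands. Trait phenotypes are drawn independently of
melanoma status given genotype, matching the analysis's treatment of
trait and disease outcomes as separate scans. All randomness flows from
one seed through named `SeedSequence` substreams; identical configs
give byte-identical TSVs.

What passing tests on these data do **not** show about real panels:
robustness to LD between tag SNPs, to population stratification, to
differential (non-random) missingness, to questionnaire
misclassification, or to case-control ascertainment that violates the
logistic sampling-invariance (e.g. survival bias).

## Numerical choices

* Normal quantile 1.959964 for 95% intervals; thresholds compared with
  strict inequality everywhere (a P value exactly at a threshold
  passes/is not flagged).
* HWE and Fisher tie comparison uses a ~1e−12 relative tolerance so
  float round-off cannot drop exactly-tied configurations.
* The Pearson 2×2 statistic uses the closed-form
  `n(ad−bc)²/(r₁r₂c₁c₂)`; zero margins are an error rather than a 0/0.
* Volcano/Manhattan coordinates are computed in a pure layer
  (`*_coords`) so plotted data are unit-testable; highlighting is
  strict (P < threshold), chromosomes order 1..22 then X.
* Problem sizes in the statistical test-suite checks: exhaustive oracle
  sweeps to n ≤ 50 (HWE), n ≤ 40 (Fisher, deduplicated by table
  symmetry) and 4-per-cell grids plus random n ≤ 30 tables (logistic);
  Monte-Carlo calibration on a 1000-SNP null panel; power/recovery on
  200/500 replicates of the study-layout single-SNP design. These sizes
  give binomial standard errors comfortably inside the asserted bands.

## Known limitations

Single-SNP additive models only (no genotypic/dominant/recessive
coding, no covariate adjustment, no interaction terms); no multi-cohort
meta-analysis machinery beyond the optional covariance argument of the
heterogeneity test; no PLINK binary formats (TSV and VCF only); no
sample-level QC (relatedness, genotype-inferred sex checks). The
reanalysis path inherits the precision of printed tables — it is a
screening tool, not a substitute for refitting on genotypes.
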