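# Methods

`rvphewas` implements a rare-variant gene-collapsing phenome-wide association
pipeline: qualifying-variant (QV) gene collapsing under configurable
dominant/recessive models, exact-test and regression association layers, a
stratified pan-ancestry combination, and empirical/permutation machinery for
study-wide significance. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic-data validation does
and does not show.

## The collapsing model

For a gene *g*, a trait *t* and a QV model *m*, the dominant collapsing test
compares the proportion of cases carrying at least one qualifying allele in
*g* against the same proportion in controls with a two-sided Fisher's exact
test on the 2×2 table (carrier/non-carrier × case/control). The recessive
model requires two qualifying alleles: a homozygous qualifying call, two or
more distinct heterozygous qualifying variants in the gene (a putative
compound heterozygote; phase is never resolved), or a hemizygous qualifying
call on the X chromosome in a male. Dominant carrier sets therefore always
contain the recessive ones.

A variant qualifies under model *m* when it passes the collapsing QC profile,
its consequence class matches the model's class, its cohort and
external-reference minor allele frequencies (MAFs) are at or below the
model's caps, and — for missense variants — any REVEL floor and MTR
(missense tolerance ratio) rule hold. REVEL/MTR rules never apply to
truncating variants, which qualify on consequence alone. "Private" models
restrict to variants carried by a single sample and absent from the external
reference. Cohort MAF is computed on post-QC genotypes as alternate alleles
over non-missing alleles, with males contributing a single allele on X.

Consequence classes are resolved from annotation term sets with the
precedence PTV > missense > other-nonsynonymous > synonymous > other, because
multi-term annotations carry no intrinsic tie-break.

The shipped model set has ten dominant models, one recessive model and one
synonymous negative-control model, spanning frequency caps from private to
5%, PTV-only versus missense-inclusive classes, and REVEL/MTR variants.
The per-model parameters are implementation defaults (the engine is fully
YAML-config-driven); the synonymous control model uses the most inclusive 5%
caps because an empirical-null model wants maximal informative test density.

## Quality control

Two threshold profiles are shipped. Call level (both): depth ≥ 10, GQ ≥ 20,
heterozygous allele-balance binomial p > 1e-6. Single-variant (ExWAS)
profile: het alternate-read fraction ≥ 0.2; site missingness < 10%;
fraction of samples failing call QC < 5%; reference 10× coverage ≥ 30% and,
when the variant is observed in the reference, pass fraction ≥ 50%.
Collapsing profile: het fraction in [0.25, 0.8]; homozygous alternate
fraction ≤ 0.8; reference 10× coverage ≥ 25% and, when observed, coverage
z-score ≥ −2 and reference site MQ ≥ 30. Site level (both): FS ≤ 60 (SNV) /
200 (indel), MQ ≥ 40, QUAL ≥ 30, RPRS ≥ −2, MQRS ≥ −8, caller status PASS.
All threshold comparisons are inclusive; "in 10% or more" style rules
fail at exactly the stated fraction. Every criterion is fail-closed: an
absent metric is a failure with an explicit reason. Reference-dependent
criteria are skipped (not failed) for variants absent from the reference.

The homozygous allele-balance cap (≤ 0.8) is applied to hom-alt calls
literally; the synthetic generator draws passing hom-alt
balances inside (0.5, 0.8] so recessive logic remains exercisable.

## Statistics

**Exact test.** Two-sided p-values use the minimum-likelihood convention:
the sum of hypergeometric point probabilities no larger than the observed
table's ("two-sided" is otherwise ambiguous for exact tests; this matches
the common R/scipy convention). Odds ratios are (a·d)/(b·c) with a
Haldane–Anscombe 0.5 correction when any cell is zero, and 95% CIs use the
Woolf log-OR normal interval — fast and stable for zero cells. The
implementation is authored here (and memoised, since a PheWAS evaluates
millions of small tables); scipy's `fisher_exact` and an exact-rational
enumeration oracle serve as independent cross-checks in the test suite.

**Regression.** Quantitative traits are analysed untransformed by OLS of the
measurement on the carrier indicator (or 0/1/2 genotype coding for the
single-variant genotypic model) with age, sex and age×sex covariates.
The bulk path uses a closed-form least-squares fit validated against
statsmodels. Genes with fewer than five measured carriers are flagged
untestable, as are singular designs; a numerically constant response returns
beta 0, p 1.

**Pan-ancestry.** Binary traits combine per-ancestry 2×2 tables with the
Cochran–Mantel–Haenszel 1-df test (no continuity correction) and the
Mantel–Haenszel common odds ratio Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ); a pooled exact
test is never used (Simpson's-paradox guard). Note the single-stratum CMH
statistic equals the Pearson chi-square times (n−1)/n — the hypergeometric
variance — which is the standard form. Quantitative pan-ancestry models use
exactly: categorical ancestry, the top five principal components, age and
sex (no age×sex term, unlike the single-ancestry model; both are implemented
as specified). Degenerate strata are dropped; an all-degenerate table
returns p = 1.

**Single-variant (ExWAS) codings.** Binary: allelic (A vs B allele counts),
dominant (AA+AB vs BB), recessive (AA vs AB+BB); quantitative: genotypic
(additive 0/1/2 — a 1-df coding; a 2-df categorical reading is also
defensible but the additive form was chosen), dominant, recessive. A variant
must be observed in at least six participants of the tested cohort.

## Phenotype harmonization

Diagnosis records live on a hierarchy (leaf → block → chapter). Every leaf
and every internal node up to the chapter becomes a candidate trait; an
internal node's cases are the union of its descendant leaves'. Controls
exclude any sample with a diagnosis in the trait's chapter. Union phenotypes
merge the case sets of related codes (same chapter), supplied as a
two-column mapping file. When the case/control female fractions differ
(exact test p < 0.05), the over-represented control sex is down-sampled to
the exact case proportion — target female count round(m·f/(1−f)) — using a
per-trait RNG stream keyed by (seed, trait id) so results do not depend on
trait order; single-sex traits keep only same-sex controls. Traits with
fewer than 30 cases are dropped. Exact-proportion matching (rather than
stopping at p ≥ 0.05) is the stricter of the two defensible readings and is
the one implemented. Raw biobank field recoding (PHESANT-style) is out of
scope; the module starts from already-binary diagnosis records.

## Cohort pruning

Kinship pruning removes, among samples in any pair with kinship > 0.0884
(KING scale, third-degree), the sample with the most above-threshold
relatives, repeatedly, ties broken lexicographically by id (deterministic;
the tie rule is a package choice). PC outlier filtering retains samples
within ±4 s.d. on each of the first four components in a single pass
(inclusive bounds; zero-variance components skipped; no iterative
re-estimation). Per-ancestry cohorts require prediction probability ≥ 0.99
for European, ≥ 0.95 otherwise, and at least 1,000 qualifying samples.

## Study-wide significance

The *n*-of-1 permutation shuffles each trait's case/control labels (or
measurements) exactly once within that trait's harmonized case∪control
universe — preserving case counts and the matched control pool — and re-runs
every non-synonymous model × gene test with the carrier matrices untouched.
The synonymous-model empirical null reads off the smallest synonymous
p-values after removing an explicit allowlist of known-real associations
(the literature-review step of identifying genuine synonymous hits cannot be
automated, hence the allowlist input). The genomic inflation factor is
λ = median(χ²₁-quantile(1−p))/0.4549 over p-values ≥ 2.6e-6 (the standard
GWAS convention for the transform; the exclusion threshold is part of the
procedure), using all tested genes. Bonferroni bookkeeping is exact integer
arithmetic over the models × phenotypes × genes grid.

## The synthetic cohort

The generator emulates every input the pipeline consumes: an annotated
variant table (consequence terms, reference MAF, REVEL, MTR, site QC
metrics), coded genotypes with per-call read metrics, a sample table (sex,
age, ancestry label and probability, five PCs), long-format diagnoses on a
3-level synthetic hierarchy (`CH##`/`BL###`/`LF####`; chapter = level-1
node; real ICD-10 content is deliberately not shipped), quantitative
measurements, and a kinship pair list.

Genotypes are drawn per variant under Hardy–Weinberg equilibrium within each
ancestry stratum, with no linkage disequilibrium — collapsing is LD-free by
construction and none of the implemented statistics consume LD. X males are
drawn haploid and stored with the homozygous code (single genotype alphabet
downstream; the VCF writer emits diploid-homozygous). Binary case status
follows a logistic model whose intercept is solved by root-finding so the
realized prevalence matches its target within Monte-Carlo error even when
planted effects shift it. Quantitative traits are carrier effect + 0.1·(age
z-score) + 0.2·(female) + unit-normal noise. Per-call read metrics are drawn
from passing ranges except for a corruption fraction (default 2%) pushed
across one randomly chosen threshold; they are generated for non-reference
calls only, since hom-ref calls carry no alternate reads and cannot toggle
carrier status. All draws flow from one seeded generator: a config and seed
determine every table byte-for-byte.

Default study conditions describe a desk-scale cohort chosen so that the
median collapsing table is statistically informative: 2,000 samples, 300
genes, ~20 segregating sites per gene, MAF-spectrum weights
0.15/0.20/0.35/0.30 over private ((0, 1/2N]), rare ([1e-4, 1e-3]),
low-frequency ([1e-3, 1e-2]) and common ([1e-2, 1e-1]) strata (log-uniform
within range), consequence probabilities 0.25/0.45/0.10/0.20 over
synonymous/missense/PTV/other, binary prevalences uniform on [0.05, 0.15]
with ~4 leaves per chapter, 54% female, ages 40–69, 90/5/3/2% ancestry
mixture. The design rule: the expected qualifying-carrier count per gene
under the synonymous model is ≈100 of 2,000 samples (≈5%), giving an
expected case-carrier cell around 15. These frequencies are deliberately
denser than a real exome cohort's; at biobank scale the same carrier counts
arise from far rarer variants.

**What passing synthetic tests do and do not show.** They demonstrate that
the pipeline's logic is correct (carrier assignment, table construction,
permutation invariances, effect recovery, confounding control) and that its
tests are never anti-conservative under the null. They do not demonstrate
calibration properties that only emerge at biobank scale: in particular, the
genomic inflation factor of a *discrete* exact test is intrinsically
deflated at n ≈ 2,000 (λ ≈ 0.65–0.8 from p-value discreteness alone, by
direct hypergeometric simulation at matched margins), while at n ≈ 270,000
it concentrates near 1. Equally, real data features absent here — linkage
disequilibrium, population substructure beyond discrete strata with PC
centroids, phenotype misclassification, batch effects — are untested.

## Numerical choices and degenerate inputs

Minlike tie comparison uses a 1e-7 relative slack to absorb floating-point
ties in hypergeometric point masses. Zero-margin tables return p = 1 with an
undefined odds ratio. The het allele-balance binomial p uses the closed
symmetric form min(1, 2·P(X ≤ min(k, n−k))). Empty annotation term sets,
unknown hierarchy codes, probability vectors off by more than 1e-12,
overlapping case/control sets and planted effects referencing absent units
all raise validation errors naming the offender. Seeded RNG streams are
keyed per trait by CRC32 of the trait id, keeping results independent of
processing order.

## Problem sizes used in validation

The shipped validation runs 20-seed null calibrations at the 2,000-sample
default scale with a three-model subset (synonymous control plus two
dominant models), 100-seed planted-effect recoveries (10,000 samples for the
binary odds-ratio experiment with a PTV-rich planted gene; 2,000 for the
quantitative beta), exhaustive exact-test enumeration over all 2×2 tables
with total ≤ 40, and exhaustive recessive-logic enumeration over all
4-sample × 3-variant genotype configurations. The acceptance script uses
3-seed calibration and 20-seed recovery summaries of the same experiments.

## Known limitations

Phase is never inferred: compound heterozygotes are putative. The MTR
percentile-band rule ranks within-gene missense variants only. The fast OLS
path assumes homoscedastic errors; no rank-based transformation is applied
to quantitative traits. Mixed-model/saddlepoint engines, FDR procedures,
multi-permutation nulls, contamination/sample-level sequencing QC and
annotation itself are out of scope.
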