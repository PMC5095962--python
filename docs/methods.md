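# Methods

## Data model

The panel consists of fully homozygous lines, so a biallelic marker has
two genotype states per line: 0 (homozygous reference) and 1
(homozygous alternate). Heterozygous calls in input VCFs are treated
as missing and counted — the association model has no heterozygous
class to put them in. Minor allele frequency is computed over
non-missing calls, over **all** lines in the panel rather than only
phenotyped lines, so marker tiers are stable across traits.

Coordinates: VCF and GFF3 input are 1-based, BED is 0-based half-open,
and all internal interval arithmetic is 0-based half-open. A gene
window of `w` bp extends the half-open gene interval on both sides, so
a marker at 0-based position p belongs to gene [s, e) iff
`s − w ≤ p < e + w`. The default window is 1 kb.

## Replicate QC and heritability

Within each (line, diet, trait) cell with ≥ 2 replicates the sample
(n−1) variance is computed; per trait, the median of those variances is
the reference, and a line strictly exceeding `fold × median`
(default 20) in any cell is removed for that trait on both diets.
Replicate variance is computed within diet arms because replicates are
batches within a diet; the paper-style filter is otherwise silent on
stratification. With only two replicates the per-line variance has a
single degree of freedom, and even a 500-fold-inflated line slips under
the 20-fold threshold roughly one time in ten; three replicates make
the rule reliable (≈ 97 % detection analytically), which is why the
recovery checks use three.

Broad-sense heritability uses the variance-partition estimator

    H² = (σ²_total − σ²_intrastrain) / σ²_total,

where σ²_total is the variance of all measurements of replicated lines
and σ²_intrastrain is the mean of per-line replicate variances. Only
lines with replicates enter either component. Sample (n−1) variances
are used throughout (unbiased at small replicate counts). Negative
estimates (σ²_intrastrain > σ²_total, possible at H² ≈ 0) are reported
as computed and flagged, never truncated. The default is per-diet
(diet is a fixed effect, not noise); a pooled mode groups cells by
(line, diet) and pools them, which folds diet main-effect variance into
σ²_total and therefore reads higher for diet-responsive traits.

The derived AL/DR ratio trait is appended per line from strain means.
Note that with a shared additive line effect the ratio's between-line
signal is second-order in the diet effect (the line effect nearly
cancels in the quotient), so the ratio's heritability is generally far
below the source trait's; in the noise-free limit it still tends to 1.

## Single-trait scan

Per marker, per-(line, diet) replicate means from both diets enter

    y = β₀ + β₁ g + β₂ d + β₃ g d + ε,   d ∈ {AL=0, DR=1},

fit by OLS; β₁ and β₃ get two-sided t-tests on n − 4 residual df.
Lines with a missing call are dropped for that marker only
(complete-case per marker). Markers that are monomorphic after
missingness, or whose genotype-by-diet design has an empty cell, are
skipped with a recorded reason; the scan never aborts. Zero-residual
(saturated) fits report p = 0 with a flag rather than NaN.

Two implementations coexist deliberately. `fit_gxd_model` fits one
marker through statsmodels. `scan_single_trait` exploits the 0/1
coding: every entry of X'X reduces to one of the four genotype-by-diet
cell counts, so the whole scan becomes a handful of masked matrix
products followed by one batched 4×4 solve across markers. The test
suite asserts agreement between the two paths and against an
independent normal-equations oracle to 1e−8.

Calibration: under the model's own null (no genetic effects of any
kind) both p-values are exactly t-distributed and empirically uniform.
With a heritable line effect shared across diets, p_genotype remains
calibrated but p_interaction becomes conservative: the line effect
cancels inside each line's AL−DR contrast while the pooled OLS residual
variance retains it, so the interaction test's denominator is
overestimated. This is a property of the published model itself, not
of this implementation; calibration checks therefore run at zero line
variance.

Variance explained is the R² of the genotype-only regression
(`y = β₀ + β₁ g`) on all lines × both diets. At loci selected for
significance it is an upper bound (Beavis/winner's-curse bias). For
cross-phenotype hits the larger of the two traits' R² is reported.

## Cross-phenotype test

For an admissible trait pair on one diet, both traits are standardized
(mean 0, sd 1, (n−1) denominator) over the lines entering the test and
stacked into one regression with per-outcome intercepts and a single
common genotype slope, fit under working independence. The slope's
variance is the line-clustered sandwich estimator, and
`β̂²/Var̂(β̂)` is referred to χ²₁. This is the defining construction
of the scaled-marginal-model family of multi-outcome tests; the
original external implementation is not reproduced numerically and
exact agreement with it is not claimed. A robust score-test variant is
available (`method="score"`).

Properties enforced by tests: one outcome (or duplicated outcomes)
reduces the test to robust simple regression; standardization absorbs
affine outcome rescaling; under the null p_joint is uniform; with equal
standardized effects on both traits the joint test's power weakly
dominates the better single-trait test.

Under missing genotypes outcomes are re-standardized over each marker's
complete-case lines, keeping the zero-mean/unit-variance property exact
per test at the cost of marker-specific scaling.

Admissible pairs: a pair is excluded when both traits share a
normalizer or when one trait is the other's normalizer — in either case
the measurements are arithmetically coupled. With traits
{starvation, mass, TAG/mass, glucose/mass} exactly the three
starvation-anchored pairs survive.

## Permutation FDR

Single-trait construction: each permutation reassigns whole phenotype
vectors (all traits, both diets) across lines, preserving each diet's
value multiset — shuffling diets independently would destroy the
gene-by-diet null structure. The full scan is re-run per permutation
and `FDR(t) = mean_i n_i(t)/n_real(t)`, reported as NA where no real
calls exist and capped at 1 for reporting (raw ratio retained). The
default threshold grid is the sorted distinct real p-values, so the FDR
is evaluable at every achievable call set.

Cross-pair construction: one genotype-to-strain shuffle per permutation
is reused across every trait pair; a locus counts when it reaches `t`
in at least one pair, and the family FDR at `t` is
`mean(n_perm)/n_true`. The two constructions are kept distinct even
though they are probabilistically equivalent here.

Ten permutations is the default; it bounds FDR resolution at roughly
0.1/n_real, and a warning says so. Permutation multiset preservation
is asserted on every run.

## The simulator

`simulate_phenotypes` draws

    y(line, diet, trait, rep) = μ + β_diet·d
        + Σ_planted (β_g·g + β_gxd·g·d) + u(line, trait) + ε,

with u drawn once per line from a multivariate normal (variance
σ²_line, trait correlation matrix C) and shared across diets — this is
what makes traits correlated across lines and diets — and ε iid
N(0, σ²_resid). Defaults emulate the target survey: 175 lines, allele
frequencies uniform on [0.05, 0.5], four traits with pairwise line-effect
correlation 0.3, diet effect 1.0, σ²_line = 0.6 / σ²_resid = 0.4
(H² ≈ 0.6, typical of highly heritable metabolic traits in inbred
panels), one biological replicate for a random half of lines and two
for the rest, intercept 10 in abstract units. `SimTruth` records the
planted effects, per-line genetic values, and the realized heritability
implied by the realized between-line variance.

What the simulator does **not** model: linkage disequilibrium,
population structure or relatedness, symbiont/inversion covariates,
batch effects, or the absolute scales and distributional shapes of real
mass/TAG/glucose measurements. Markers are independent Bernoulli
columns. Passing recovery tests therefore demonstrates correctness of
the statistics under the model's own assumptions, not robustness to the
confounders real panels carry.

Problem sizes in the recovery checks (chosen to exercise the study's
scale while keeping the default suite quick): calibration at 200 lines ×
1000 markers; FDR truth recovery at 200 lines × 2500 markers with 25
planted markers each explaining ~15 % of the non-genetic background
variance (25 markers at 15 % of total variance would exceed 100 %,
so the background reading is the consistent one); heritability recovery
at 100 lines × 3 replicates × 50 seeds; power comparisons over 300
draws at 200 lines; enrichment calibration over 200 random terms of 500
genes and 500 confound replicates.

## Enrichment

Genes are scored by the minimum p among their assigned markers (ties
broken by chromosome, start, then gene id for determinism), ranked
ascending, and each term with **strictly more than** `min_members`
(default 10) scored genes is tested by logistic regression of
membership on normalized rank (rank/n) with log gene length as a
covariate. Long genes collect more markers and hence better
extreme-value scores; the covariate absorbs that bias, and simulations
with a planted length–rank confound and no true enrichment keep the
rank coefficient's false-positive rate at its nominal level. The
covariate can be disabled for comparison and is dropped automatically
when lengths are constant (it would be collinear with the intercept).

When the ML fit separates (a term occupying an exact rank prefix) or
fails to converge, the term is refit by Firth's Jeffreys-prior
penalized logistic regression (implemented in-package) and flagged;
its p-value comes from the penalized likelihood-ratio test, since the
Wald statistic is uninformative under separation. Benjamini–Hochberg
correction is applied across all tested terms. Annotations are taken
as given (no ontology-graph propagation); enrichment depends on ranks
only, so it is invariant to monotone transformations of gene scores.

## Pipeline and reproducibility

`run_pipeline` executes QC → heritability → single-trait scans (both
MAF tiers) → cross-phenotype scans per diet over admissible pairs →
permutation FDR (both constructions) → enrichment, writing per-stage
TSVs, a resolved-config YAML, and a sorted-key JSON summary. All
randomness flows from explicit seeds; identical config + seed yields
byte-identical summaries and fixture bundles. Stage-level logging
records per-marker skip tallies; nothing is dropped silently.

## Known limitations

- No mixed-model (kinship) correction; the scan reproduces the plain
  OLS model as published, so cryptic relatedness in real data would
  inflate test statistics.
- The interaction test is conservative in the presence of heritable
  line effects (see above); a mixed model or line-paired contrast would
  restore power but is out of scope.
- Permutation FDR at 10 permutations is coarse; raise `n_perm` for
  finer resolution.
- The cross-phenotype implementation matches the scaled-marginal-model
  construction, not any specific external package's numerics.
- VCF writing covers the minimal fields this pipeline consumes (GT
  only).
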