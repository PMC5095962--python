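# crossphen

Gene-by-diet and cross-phenotype association mapping for panels of
homozygous inbred lines, with permutation-based false-discovery-rate
control, broad-sense heritability, and rank-based gene-set enrichment.

## The problem

Panels of fully inbred, sequenced lines — the Drosophila Genetic
Reference Panel (DGRP) being the canonical example — let the same
genotype be phenotyped repeatedly and across environments. A typical
survey measures several metabolic traits (starvation resistance, body
mass, mass-normalized triglyceride and glucose content) on two diets:
ad libitum (AL) and dietary restriction (DR). Power at panel scale
(~150–200 lines) is the central obstacle, and this package implements
the three strategies such surveys use to fight it:

1. **Gene-by-diet scans.** For each biallelic marker, replicate-mean
   phenotypes from all lines on both diets enter one OLS fit,

   ```
   y = β₀ + β₁·g + β₂·d + β₃·g·d + ε
   ```

   with `g ∈ {0,1}` the homozygous genotype and `d ∈ {0,1}` the diet
   (AL = 0, DR = 1). `p_genotype` tests β₁ = 0 and `p_interaction`
   tests β₃ = 0 (two-sided t, n − 4 df). Marker tiers at minor allele
   frequency ≥ 5 % and ≥ 25 %, and an optional restriction to markers
   within 1 kb of disease-homolog genes, trade genome coverage for
   per-test power.

2. **Cross-phenotype tests.** A variant affecting two traits at once is
   tested jointly: both traits (per diet) are standardized, stacked,
   and a single common effect β of genotype is fit under working
   independence; its variance comes from the line-clustered sandwich
   estimator and `β̂²/Var̂(β̂)` is referred to χ²₁. Pairs of traits
   sharing a normalizer (or where one trait is the other's normalizer)
   are inadmissible — with the four survey traits exactly the three
   starvation-anchored pairs remain.

3. **Permutation FDR.** At a p-value threshold `t`,
   `FDR(t) = mean_i n_i(t) / n_real(t)` over permutations `i` that
   shuffle phenotype vectors across lines while retaining the diet
   assignment (single-trait scans) or shuffle the genotype-to-strain
   assignment reused across all trait pairs (cross-pair family).

Around the scans: replicate QC (a line whose replicate variance exceeds
20× the panel median is dropped for that trait), broad-sense
heritability `H² = (σ²_total − σ²_intrastrain)/σ²_total`, per-locus
variance explained (genotype-only R², an upper bound via the Beavis
effect), and gene-set enrichment by logistic regression of term
membership on normalized gene rank with a log gene-length covariate,
Benjamini–Hochberg corrected.

Because such surveys rarely deposit raw phenotypes, the package ships a
first-class simulator (`crossphen.simulate`) that generates genotype
panels and two-diet replicated phenotypes with known planted effects,
so every stage is testable end to end against ground truth.

## Worked example

Simulate a survey-scale study (175 lines, 2000 markers, four correlated
traits, mixed 1–2 replicates), then run heritability and a single-trait
scan:

```
$ crossphen simulate --n-lines 175 --n-markers 2000 --seed 42 --out demo
$ crossphen heritability --phenotypes demo/phenotypes.tsv --diet AL --out demo/h2.tsv
           trait diet  sigma2_total  sigma2_intrastrain       H2  n_lines
glucose_per_mass   AL      0.893051            0.361664 0.595025       88
            mass   AL      1.030053            0.411639 0.600371       88
      starvation   AL      1.097409            0.362567 0.669615       88
    tag_per_mass   AL      1.028309            0.328806 0.680246       88

$ crossphen scan-single --genotypes demo/genotypes.vcf \
    --phenotypes demo/phenotypes.tsv --trait starvation --out demo/scan.tsv
1970 markers tested -> demo/scan.tsv
```

The heritability table partitions phenotypic variance among the 88
replicated lines: H² ≈ 0.6–0.7 says most between-measurement variance
is genetic, matching the simulator's default line variance of 0.6.
The scan table holds one row per marker; its top rows at this null
seed (no planted effects) are chance associations around p ≈ 1e-3,
exactly what ~2000 independent tests should produce:

```
     marker  beta_genotype  beta_diet  beta_interaction  p_genotype  p_interaction       r2
chr1:163601       0.479543   1.039797         -0.081901    0.001322       0.696037 0.037534
chr1:262601      -0.794081   0.971118          0.444043    0.001348       0.202126 0.023543
```

`beta_diet ≈ 1` recovers the simulated diet main effect. The
`run-all` subcommand chains QC → heritability → both scan tiers →
cross-phenotype scans → permutation FDR (both constructions) →
enrichment, writing every stage's TSV plus a seeded, byte-reproducible
`summary.json`.

Library use mirrors the CLI: `io.read_genotypes`, `qc.strain_means`,
`scan.scan_single_trait`, `cross.scan_cross_phenotype`,
`fdr.estimate_fdr_single`, `enrich.rank_enrichment`,
`pipeline.run_pipeline`.

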