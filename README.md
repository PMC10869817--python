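# eqtac

Mapping **expression quantitative trait accessible chromatin (eQTac)**:
regulatory open-chromatin elements whose *sequence-predicted*,
genotype-dependent accessibility correlates with gene expression across
individuals.

Population-scale chromatin profiling (ATAC-seq on every donor) is rarely
available, but genotypes and RNA-seq usually are. This package predicts each
individual's local chromatin accessibility from their alleles using a gapped
k-mer sequence model trained on a single reference set of accessibility
peaks, and then tests those predictions against expression in *cis* — so
regulatory elements can be linked to target genes with genotype and
expression data alone. It is written for statistical geneticists and
regulatory genomicists; the library API is the primary interface, with a
thin `eqtac` command line on top and runnable walkthroughs in `examples/`.

## The method

1. **Accessibility model.** A linear SVM over the explicit gapped k-mer
   feature space (word length *l*, *k* informative columns; features =
   C(l,k)·4^k mask×word pairs, reverse-complement collapsed, cosine-
   normalized) is trained on 100-bp summit-centered peak sequences versus
   genome background matched on GC content and repeat fraction.
   Hyper-parameters are chosen by 3-fold cross-validated ROC AUC.

2. **Potential regulatory elements (PREs).** The ±250 bp window around each
   peak summit, kept only if it overlaps no indel, has no SNP pair closer
   than 10 bp, and contains more than one mutually independent SNP
   (LD r² < 0.3, greedy pruning on dosage correlation).

3. **Chromatin accessibility score.** For each SNP *i* in a PRE the model
   scores the two 19-bp allele windows (9 bp of flank each side), giving
   S_ij; with G_ij the individual's dosage of allele *j*, the per-individual
   score of the PRE is

   CAS = Σᵢ Σⱼ S_ij · G_ij .

4. **Association and FDR.** For every PRE–gene pair with the summit within
   1 Mb of the TSS, fit `expression ~ β₁·CAS + covariates` (OLS, two-sided
   t-test on β₁) on filtered, TMM-scaled, inverse-normal-transformed
   expression. Individual labels of the expression matrix are permuted 100
   times to form a null p-value pool; the significance threshold is the
   largest observed p with

   FDR(t) = frac_permuted(p ≤ t) / frac_observed(p ≤ t) ≤ 0.05

   (with an add-one correction on the permuted fraction). A companion
   nominal per-SNP cis-eQTL scan with BH q-values identifies eQTac regions
   that contain no individually significant variant.

Expression QC implements the per-sample outlier statistic
D_i = (r̄_i − mean r̄) / median|r̄_i − mean r̄|, where r̄_i is sample *i*'s
average pairwise log-TPM correlation; samples with D < −5 are dropped.

A fully seeded synthetic-data generator (`eqtac.simulate`) produces a small
genome with motif-bearing peaks, motif-disrupting SNPs, LD-structured
genotypes, covariates and negative-binomial expression with planted
CAS-mediated effects — every stage of the pipeline is testable offline, and
the generator's ground truth makes recovery measurable.

## Worked example

`examples/04_map_eqtac.py` runs the whole chain on a simulated cohort of
200 individuals, 300 genes and 100 peaks (effect size β = 1 on the
standardized oracle accessibility score, noise sd = 1):

```
accessibility model CV AUC: 0.921
PREs retained: 92 / 100
pairs tested: 25668; p threshold at FDR 0.05: 0.000124; significant: 65
planted effects recovered: 60 / 60
```

The model separates motif-bearing summits from matched background (AUC
0.92); 8 of 100 candidate PREs are removed by the indel/spacing/LD filters
the generator deliberately violates; the permutation calibration sets the
genome-wide p threshold (1.2×10⁻⁴ here), and all 60 genes with a planted
accessibility-mediated effect are flagged at FDR 0.05. The other examples
walk through simulation (`01`), expression QC (`02`) and allele-level
scoring (`03`).

The same pipeline is available from the shell:

```bash
eqtac simulate --seed 42 --out cohort/
eqtac run --config config.yaml        # stages: simulate|qc|train|cas|map
```

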