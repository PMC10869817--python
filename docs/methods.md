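# Methods

This note records the model, the numerical conventions, and the design
choices behind the package, in the spirit of a statistical supplement.

## Model overview

The package infers genotype-dependent chromatin accessibility without
per-individual chromatin assays. The causal model it assumes is:

    sequence (alleles) -> local chromatin accessibility -> gene expression

A sequence classifier trained once, on a reference set of accessible
regions, supplies the sequence→accessibility map; dosage-weighting its
allele scores supplies each individual's predicted accessibility of a
candidate element; ordinary linear regression against expression, with an
empirical permutation null, supplies the element→gene links.

## Gapped k-mer sequence model

**Feature map.** A sequence of length L contributes one count per
(l-window, position-mask) pair: masks are the C(l,k) choices of k
informative columns among l, and the feature index is (mask, k-letter
word). The space is realized explicitly — C(l,k)·4^k features before
strand collapsing — rather than through a d-truncated kernel
approximation. Exactness buys bit-reproducible scores and an integer-exact
oracle: the dot product of two feature vectors equals a brute-force count
of matching gapped k-mer pairs, which the tests verify literally. The
mismatch-truncation parameter `d` is accepted for interface parity and has
no effect; `l <= 12` keeps the explicit space tractable.

**Strand handling.** Accessibility is unstranded, so reverse-complement
collapsing is on by default: each (mask, word) feature is mapped to the
canonical member of its strand-equivalence class (e.g. the 16 2-mers fall
into 10 classes). Collapsed featurization is exactly invariant to
reverse-complementing the input.

**Normalization.** Feature vectors are L2 (cosine) normalized before the
SVM — the usual normalization of gapped k-mer kernels. Raw counts scale
with sequence length and low-complexity content, which otherwise dominates
the margin geometry and makes the regularization path degenerate.

**Training.** Positives are 100-bp summit-centered peak sequences;
negatives are drawn uniformly from the genome, rejected if they overlap a
caller-supplied relaxed accessibility set (default: the peak set padded
±500 bp, standing in for a lenient-threshold peak call) and accepted into
fixed (GC decile × repeat-fraction decile) bins until each bin matches its
positive count (repeat fraction = soft-masked lowercase proportion). The
classifier is a hinge-loss linear SVM with balanced class weights; C is
chosen from {0.1, 1, 10} by mean 3-fold cross-validated ROC AUC, and the
chosen point is refit on all data. Windows containing ambiguous bases are
skipped, not imputed. Training is deterministic given the seed.

## PREs and the accessibility score

A candidate element is the closed 501-bp window [summit−250, summit+250].
Candidates are dropped, with a recorded reason, if (i) any indel or
insertion overlaps the window (allele windows must stay length-consistent),
(ii) any two SNPs lie closer than 10 bp (their windows would perturb each
other's scores), or (iii) fewer than two SNPs survive greedy LD pruning at
r² < 0.3 — otherwise the element's score is collinear with a single variant
or haplotype and adds nothing over a plain eQTL. Pruning is greedy
left-to-right on position, with r² computed from sample dosage correlation
(no external reference panel).

Each surviving SNP is scored on its two allele windows — 9 bp of reference
flank on each side of the focal base, ref or alt substituted at the center
(19 bp, enough to contain every l=10 window through the SNP). Windows may
extend past the element boundary; SNPs whose window would leave the contig
are dropped from that element only. The per-individual score is the
dosage-weighted sum over SNPs and alleles,

    CAS = sum_i sum_j S_ij G_ij,   G_ref = 2 − g,  G_alt = g,

with fractional (imputed) dosages allowed. CAS is linear in dosage; the
tests assert the exact perturbation identity (a unit change of one
individual's dosage moves their CAS by S_alt − S_ref) and invariance to
relabeling ref/alt together with g → 2 − g.

## Expression processing

- **Sample outliers.** Pairwise Pearson correlation of log2(TPM+1)
  (Spearman available); r̄_i averages row i of the correlation matrix over
  all n samples, self term included — as the formula is printed; excluding
  it shifts every r̄_i by a constant and rescales the MAD identically, so
  D is unchanged, and an `exclude_self` option exposes the variant. D_i
  divides the deviation from the grand mean by the median absolute
  deviation; D < −5 flags a sample. All samples equicorrelated (MAD = 0)
  is a degenerate input and raises.
- **Gene filters.** Keep genes with TPM ≥ 0.1 in ≥ 20% of samples *and*
  raw counts ≥ 6 in ≥ 20% of samples; all thresholds inclusive.
- **TMM.** Between-sample scaling follows the published trimmed mean of
  M-values estimator and matches the edgeR reference implementation to
  print precision (verified in a test via Rscript): reference = library
  whose upper quartile of count/libsize is closest to the mean upper
  quartile; genes nonzero in both libraries contribute M and A values;
  two-sided trims of 30% on M and 5% on A; surviving M averaged with
  inverse asymptotic-variance weights; factors normalized to geometric
  mean 1.
- **INT.** Per gene across samples: Φ⁻¹((rank − 0.5)/n) with midranks for
  ties (Blom's 3/8 offset available). Rows with ties are no longer exactly
  mean-zero; rank order is always preserved.

## Association mapping and permutation FDR

Pairs are all (element, gene) with the summit within 1 Mb of the
strand-aware TSS, boundary inclusive, distance signed negative upstream.
The regression `expression ~ β₁·CAS + covariates` is ordinary least
squares with a two-sided t-test on β₁ (df = n − parameters). The scan is
vectorized by residualizing both sides against the covariate design once
(Frisch–Waugh–Lovell); a test asserts equality with the single-pair fit to
1e-10. CAS is centered and scaled per element before regression — this
leaves t and p unchanged and puts β on a per-SD scale. Covariates beyond
those supplied can include the top principal components of the
gene-centered expression matrix (`hidden_factors`), standing in for
latent technical structure.

The null is built by permuting individual labels of the expression matrix:
one shared permutation per replicate across all genes (default 100
replicates), which preserves gene–gene correlation in the null and keeps
covariates and CAS attached to the individuals; a per-gene mode exists
behind a flag. The FDR at threshold t is the permuted proportion of
p ≤ t over the observed proportion; the permuted proportion carries an
add-one correction (1 + count)/(pool + 1), the standard guard against
reading a zero permuted count in the extreme tail as FDR = 0. The reported
threshold is the largest *observed* p with estimated FDR at or below the
target; zero-variance elements are excluded from observed and permuted
pools symmetrically. The companion nominal cis-eQTL scan reuses the same
regression core with dosage in place of CAS and applies
Benjamini–Hochberg across pairs — a desk-scale stand-in for
adaptive-permutation eQTL machinery, used only to label elements lacking
any individually significant variant.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
any particular organism:

- **Genome/peaks.** I.i.d. background with soft-masked "repeat" tracts
  (~10% of the background); each peak is a 501-bp locus with an exact
  central motif instance (consensus TGACTCA) at the summit plus 0–2
  nearby instances mutated at 8% per position. Planted filter violations
  (indel overlap, <10 bp SNP spacing, single-SNP, perfect-LD pair) are
  counted in the ground truth so drop-reason tallies are checkable.
- **Genotypes.** Peak SNPs are one motif-disrupting SNP (reference allele
  = consensus base, alternate a mismatch) plus one neutral SNP, drawn
  independently; intergenic SNPs come in LD blocks from a stationary
  two-state Markov haplotype chain with adjacent-allele correlation ρ
  (default 0.8). The minor-allele frequency is drawn per block — a shared
  block frequency is what makes the Markov construction achieve ρ exactly
  and mirrors the shared history of alleles on a haplotype block.
  Genotypes are sums of two independent haplotypes, so adjacent-SNP
  genotype r² ≈ ρ².
- **Expression.** The oracle accessibility score uses best-alignment
  motif-match fractions as allele weights in the same dosage-weighted sum
  as the pipeline — deliberately independent of the learned SVM, so the
  end-to-end test validates the model rather than assuming it. Effect
  genes (default 20%) add β × standardized-oracle-CAS of one valid peak to
  their latent log expression, plus covariate loadings and N(0, sd²)
  noise; counts are negative binomial (size 10) around per-sample scaled
  means, TPM uses random gene lengths, and a configurable number of
  outlier samples replaces the shared structure with inflated independent
  noise. Some genes are built to fail the expression filters.

Default conditions (200 individuals, 300 genes, 100 peaks, β = 1,
sd = 1) are the study conditions of the end-to-end experiment; the
desk-scale classifier there uses l=6, k=4 so that the whole experiment
runs in seconds (the paper-scale l=10, k=6 space, 860,160 features, is the
`GkmParams` default and fully supported).

**What the simulation does not emulate:** realistic human LD panels and
allele-frequency spectra, read-level noise, peak-calling artifacts,
trans-regulation, and TF grammar beyond a single consensus motif. Passing
the end-to-end test shows the pipeline recovers planted sequence-mediated
effects under its own assumptions; it does not certify performance on real
cohorts.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; VCF positions convert on
read; narrowPeak summits use the offset column, plain BED uses the interval
midpoint. Dosages come from DS when present, else hard GT sums; variants
above a missingness cap (default 10%) are dropped, and elements whose CAS
is missing for more than 10% of individuals are omitted. Sample sets are
intersected across inputs, ordered by the VCF; an empty intersection is an
error listing the inputs. Ties in LD pruning resolve toward the
left-most SNP; FDR threshold ties resolve toward the smaller p. All
randomness flows from a single integer seed through NumPy's PCG64
generator; two runs of the same configuration produce byte-identical
output tables.

## Known limitations

- The explicit feature space caps l at 12; genome-scale training sets
  (10^5 sequences) would need the usual kernel/truncation machinery.
- The permutation threshold search is a step function of the observed
  p-values; with few pairs the realized FDR is noisy around the target.
- PEER-style factor inference is replaced by expression PCs.
- Phased haplotype scoring of the full 501-bp element is out of scope:
  only SNP windows are scored, as in the underlying accessibility-score
  definition.
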