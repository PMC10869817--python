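"""Generate a synthetic cohort and look at what was planted.

The generator builds the full causal chain the method assumes: a genome
with motif-bearing accessibility peaks, SNPs that do or do not disrupt the
motif, LD-structured genotypes, and expression in which a subset of genes
is driven by the (oracle) accessibility of one peak.
"""

from collections import Counter

from eqtac import SimConfig, simulate

sim = simulate(SimConfig(seed=42, n_individuals=100, n_genes=120, n_peaks=40,
                         genome_length=120_000, n_lowexpr_genes=8))

print(f"genome: {len(sim.genome[sim.config.chrom]):,} bp on {sim.config.chrom}")
print(f"peaks: {len(sim.peaks)} (categories: {dict(Counter(sim.truth.peak_category.values()))})")
print(f"variants: {len(sim.variants)} SNPs, {len(sim.excluded)} indels")
print(f"expression: {sim.counts.shape[0]} genes x {sim.counts.shape[1]} samples")
print(f"planted effect genes: {len(sim.truth.effect_genes)} "
      f"(beta = {sim.config.beta} on the standardized oracle accessibility score)")

# Everything can also be written in standard formats (FASTA/VCF/BED/TSV):
#   sim.write("cohort_dir")
# The peak categories above are the PRE-filter violations planted on purpose:
# 'close' peaks carry SNPs <10 bp apart, 'highld' peaks a perfect-LD pair,
# 'single' peaks one SNP, 'indel' peaks an overlapping indel.
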