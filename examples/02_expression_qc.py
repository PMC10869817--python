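"""Expression quality control: sample outliers, gene filters, normalization.

The outlier statistic D_i measures how far each sample's average pairwise
correlation sits from the cohort (in median-absolute-deviation units);
samples with D < -5 are conventionally discarded.  Genes must reach 0.1 TPM
and 6 reads in at least 20% of samples; surviving counts are TMM-scaled and
each gene is inverse-normal-transformed across samples.
"""

import numpy as np

from eqtac import SimConfig, simulate
from eqtac.expression import (correlation_outlier_stat, filter_genes,
                              prepare_expression, tmm_factors)

# plant two grossly noisy samples to give the QC something to find
sim = simulate(SimConfig(seed=7, n_individuals=80, n_genes=200, n_peaks=20,
                         genome_length=60_000, n_outlier_samples=2))

report = correlation_outlier_stat(np.log2(sim.tpm + 1.0))
print("lowest-D samples:")
print(report.table.nsmallest(4, "D").round(3))
print(f"flagged as outliers: {report.outliers} "
      f"(planted: {sim.truth.outlier_samples})")

kept = filter_genes(sim.counts, sim.tpm)
print(f"\ngenes passing expression filters: {len(kept)} / {sim.counts.shape[0]}")

factors = tmm_factors(sim.counts)
print(f"TMM scale factors: min {factors.min():.3f}, max {factors.max():.3f} "
      f"(geometric mean 1 by construction)")

expr = prepare_expression(sim.counts, sim.tpm)
print(f"normalized matrix: {expr.shape[0]} genes x {expr.shape[1]} samples, "
      f"per-gene values are N(0,1) quantiles")
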