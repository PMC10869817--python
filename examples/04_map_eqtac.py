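"""End-to-end eQTac scan: from genotypes and peaks to significant PRE-gene pairs.

Potential regulatory elements (+/-250 bp of each summit) are filtered for
indels, SNP spacing and LD-independence; each retained PRE gets a
per-individual chromatin accessibility score CAS = sum_ij S_ij * G_ij
(allele window score x allele dosage); expression is regressed on CAS with
covariates, and significance is calibrated by permuting individual labels
of the expression matrix 100 times.
"""

import numpy as np

from eqtac import (GkmParams, SimConfig, TrainingSet, build_negative_set,
                   cas_matrix, extract_positive_set, map_eqtac, select_pres,
                   simulate, train_classifier)
from eqtac.expression import prepare_expression

sim = simulate(SimConfig(seed=1))  # 200 individuals, 300 genes, 100 peaks

positives = extract_positive_set(sim.genome, sim.peaks)
negatives = build_negative_set(
    sim.genome, positives,
    [(p.chrom, p.start - 500, p.end + 500) for p in sim.peaks], seed=1)
model = train_classifier(TrainingSet(positives, negatives),
                         params_grid=GkmParams(l=6, k=4), folds=3, seed=1)
print(f"accessibility model CV AUC: {model.cv_auc:.3f}")

pres = select_pres(sim.peaks, sim.variants, sim.excluded,
                   ld_r2=0.3, min_gap=10)
kept = [p for p in pres if p.kept]
print(f"PREs retained: {len(kept)} / {len(pres)}")

cas, _ = cas_matrix(pres, model, sim.genome, sim.samples, flank=9)
expr = prepare_expression(sim.counts, sim.tpm)
results, fdr = map_eqtac(kept, sim.genes, expr, cas, sim.covariates,
                         cis_window=1e6, n_perm=100, fdr=0.05, seed=1)
n_sig = int(results["significant"].sum())
print(f"pairs tested: {len(results)}; p threshold at FDR 0.05: "
      f"{fdr.p_threshold:.3g}; significant: {n_sig}")

# compare against the generator's ground truth
name_of = {pk.summit: pk.name for pk in sim.peaks}
pre_of_peak = {name_of[p.summit]: p.pre_id for p in kept}
flagged = set(zip(results[results.significant].pre_id,
                  results[results.significant].gene_id))
hits = sum((pre_of_peak.get(i["peak"]), g) in flagged
           for g, i in sim.truth.effect_genes.items())
print(f"planted effects recovered: {hits} / {len(sim.truth.effect_genes)}")
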