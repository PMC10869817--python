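"""Self-contained synthetic data for the accessibility-QTL pipeline.

The generator emulates the causal chain the method assumes: a small genome
carries motif-bearing accessibility peaks; SNPs inside peaks either disrupt
a planted motif base (changing the locus's sequence-encoded accessibility)
or are neutral; LD-structured genotypes give each individual an allele
configuration; and gene expression is driven by an *oracle* accessibility
score — motif-match counting on each individual's alleles, independent of
any learned model — plus covariate structure and noise.  Counts are drawn
negative-binomially so TMM scaling and expression filters are exercised, and
a configurable number of outlier samples (inflated noise) exercises the
sample QC statistic.

Every quantity needed to grade the pipeline (which peaks violate which PRE
filter, which SNPs disrupt motifs, which genes carry a planted effect, the
oracle scores themselves) is recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExcludedVariant,
    GeneAnnotation,
    PeakRecord,
    VariantRecord,
    write_fasta,
    write_matrix,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions of the headline end-to-end experiment:
    200 individuals, 300 genes, 100 peaks, planted effect size beta=1 on a
    unit-variance oracle accessibility score against unit latent noise.
    """

    seed: int
    genome_length: int = 400_000
    chrom: str = "chr1"
    n_peaks: int = 100
    motif: str = "TGACTCA"
    motif_mut_rate: float = 0.08
    max_extra_motifs: int = 2
    repeat_rate: float = 0.10
    n_individuals: int = 200
    ld_block_size: int = 5
    ld_rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    n_intergenic_blocks: int = 30
    n_genes: int = 300
    effect_fraction: float = 0.2
    beta: float = 1.0
    noise_sd: float = 1.0
    n_covariates: int = 2
    covariate_loading_sd: float = 0.5
    n_outlier_samples: int = 0
    outlier_noise_scale: float = 8.0
    nb_size: float = 10.0
    n_lowexpr_genes: int = 20
    n_indel_peaks: int = 2
    n_close_snp_peaks: int = 2
    n_single_snp_peaks: int = 2
    n_high_ld_peaks: int = 2
    flank: int = 9
    rng_algorithm: str = "PCG64"  # np.random.default_rng bit generator

    def __post_init__(self) -> None:
        if self.genome_length < self.n_peaks * 2000:
            raise ValueError(
                f"infeasible packing: genome_length {self.genome_length} < "
                f"{self.n_peaks} peaks x 2 kb"
            )
        for rate in (self.motif_mut_rate, self.repeat_rate, self.effect_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Everything needed to compute oracle scores and grade the pipeline."""

    peak_category: dict = field(default_factory=dict)  # peak name -> valid/indel/...
    motif_positions: dict = field(default_factory=dict)  # peak name -> [starts]
    disrupting_snps: dict = field(default_factory=dict)  # vid -> peak name
    snp_peak: dict = field(default_factory=dict)  # vid -> peak name (peak SNPs)
    snp_target_maf: dict = field(default_factory=dict)  # vid -> frequency drawn
    oracle_allele_scores: dict = field(default_factory=dict)  # vid -> (s_ref, s_alt)
    oracle_cas: dict = field(default_factory=dict)  # peak name -> per-individual list
    effect_genes: dict = field(default_factory=dict)  # gene_id -> {peak, beta}
    lowexpr_genes: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)
    n_planted_indels: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimData:
    """One fully simulated cohort, in memory."""

    config: SimConfig
    genome: dict
    peaks: list
    variants: list
    excluded: list
    samples: list
    counts: pd.DataFrame
    tpm: pd.DataFrame
    covariates: pd.DataFrame
    genes: list
    truth: GroundTruth

    def dosage_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.vstack([v.dosages for v in self.variants]),
            index=[v.vid for v in self.variants],
            columns=self.samples,
        )

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        with open(out / "peaks.narrowPeak", "w") as fh:
            for p in self.peaks:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t0\t-1\t-1\t"
                    f"{p.summit - p.start}\n"
                )
        write_vcf(out / "genotypes.vcf", self)
        write_matrix(self.counts, out / "counts.tsv", "gene_id")
        write_matrix(self.tpm, out / "tpm.tsv", "gene_id")
        write_matrix(self.covariates, out / "covariates.tsv", "covariate")
        with open(out / "genes.tsv", "w") as fh:
            fh.write("gene_id\tchrom\ttss\tstrand\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")
        self.truth.to_json(out / "ground_truth.json")


# -- oracle accessibility -------------------------------------------------


def motif_match_score(window: str, motif: str) -> float:
    """Best fractional consensus match of ``motif`` over alignments in ``window``."""
    w = window.upper()
    m = len(motif)
    if len(w) < m:
        return 0.0
    return max(
        sum(a == b for a, b in zip(w[i : i + m], motif)) / m
        for i in range(len(w) - m + 1)
    )


def oracle_allele_scores(snp: VariantRecord, genome: dict, motif: str, flank: int):
    seq = genome[snp.chrom][snp.pos - flank : snp.pos + flank + 1].upper()
    ref_win = seq
    alt_win = seq[:flank] + snp.alt.upper() + seq[flank + 1 :]
    return motif_match_score(ref_win, motif), motif_match_score(alt_win, motif)


def oracle_cas(snps, allele_scores: dict) -> np.ndarray:
    """Eq.-style dosage-weighted sum using motif-match scores as weights."""
    cas = None
    for snp in snps:
        s_ref, s_alt = allele_scores[snp.vid]
        term = s_ref * (2.0 - snp.dosages) + s_alt * snp.dosages
        cas = term if cas is None else cas + term
    return cas


# -- stage 1: genome and peaks -------------------------------------------


def simulate_genome_peaks(config: SimConfig, rng=None):
    """Background genome with soft-masked repeat tracts and motif-bearing peaks.

    Each peak is a 501-bp locus whose summit sits at the center of an exact
    central motif instance; 0-``max_extra_motifs`` additional instances are
    planted nearby with per-position mutation at ``motif_mut_rate``.
    """
    rng = rng or config.rng()
    L, n = config.genome_length, config.n_peaks
    seq = rng.choice(4, size=L)
    motif = config.motif
    m_idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in motif])
    slot = L // n
    truth = GroundTruth()
    peaks = []
    for i in range(n):
        summit = i * slot + slot // 2
        name = f"peak_{i:04d}"
        positions = []
        # exact central instance, centered on the summit
        c0 = summit - len(motif) // 2
        seq[c0 : c0 + len(motif)] = m_idx
        positions.append(int(c0))
        for _ in range(int(rng.integers(0, config.max_extra_motifs + 1))):
            off = int(rng.integers(40, 220)) * int(rng.choice([-1, 1]))
            start = summit + off
            inst = m_idx.copy()
            mut = rng.random(len(motif)) < config.motif_mut_rate
            inst[mut] = rng.integers(0, 4, size=mut.sum())
            seq[start : start + len(motif)] = inst
            positions.append(int(start))
        peaks.append(PeakRecord(config.chrom, summit - 250, summit + 251, summit, name))
        truth.motif_positions[name] = positions  # central (exact) instance first

    chars = _BASES[seq].copy()
    # lowercase repeat tracts in the background, clear of peak loci
    target = int(config.repeat_rate * L)
    covered = 0
    guard = 0
    while covered < target and guard < 10_000:
        guard += 1
        start = int(rng.integers(0, L - 500))
        length = int(rng.integers(100, 500))
        end = min(start + length, L)
        if any(start < p.end + 300 and end > p.start - 300 for p in peaks):
            continue
        chars[start:end] = np.char.lower(chars[start:end])
        covered += end - start
    genome = {config.chrom: "".join(chars)}
    return genome, peaks, truth


# -- stage 2: genotypes ---------------------------------------------------


def _markov_haplotypes(n_hap: int, p: float, rho: float, n_snps: int, rng) -> np.ndarray:
    """Stationary two-state Markov chain along SNPs of one LD block.

    All SNPs in the block share minor-allele frequency ``p``; adjacent
    alleles on a haplotype have correlation exactly ``rho``.
    """
    h = np.empty((n_snps, n_hap), dtype=np.int8)
    h[0] = rng.random(n_hap) < p
    for j in range(1, n_snps):
        stay1 = p + rho * (1 - p)  # P(1 | previous 1)
        go1 = p * (1 - rho)  # P(1 | previous 0)
        u = rng.random(n_hap)
        h[j] = np.where(h[j - 1] == 1, u < stay1, u < go1)
    return h


def _genotypes_from_p(n_ind: int, p: float, rng) -> np.ndarray:
    return (rng.random(n_ind) < p).astype(np.float64) + (rng.random(n_ind) < p)


def simulate_genotypes(config: SimConfig, genome: dict, peaks, truth: GroundTruth, rng):
    """SNPs inside and between peaks, planted filter violations, indels.

    Peak categories: ``valid`` peaks carry one motif-disrupting SNP (its ref
    allele is the planted consensus base, its alt a mismatch) plus one
    neutral SNP; violation peaks exercise the PRE filters (indel overlap,
    <10 bp spacing, a single SNP, perfect-LD SNP pairs).  Intergenic LD
    blocks use a stationary Markov copula at correlation ``ld_rho``.
    """
    n_ind = config.n_individuals
    chrom = config.chrom
    gseq = genome[chrom]
    motif = config.motif
    lo, hi = config.maf_range

    categories = ["valid"] * config.n_peaks
    special = (
        ["indel"] * config.n_indel_peaks
        + ["close"] * config.n_close_snp_peaks
        + ["single"] * config.n_single_snp_peaks
        + ["highld"] * config.n_high_ld_peaks
    )
    slots = rng.permutation(config.n_peaks)[: len(special)]
    for cat, idx in zip(special, slots):
        categories[idx] = cat

    variants: list[VariantRecord] = []
    excluded: list[ExcludedVariant] = []
    used_positions: set[int] = set()

    def other_base(ref: str) -> str:
        return str(rng.choice([b for b in "ACGT" if b != ref.upper()]))

    def add_snp(pos: int, ref_from_genome: bool, peak_name: str | None,
                disrupting: bool, dosages=None, maf=None) -> VariantRecord:
        while pos in used_positions:
            pos += 1
        used_positions.add(pos)
        ref = gseq[pos].upper()
        alt = other_base(ref)
        if maf is None:
            maf = float(rng.uniform(lo, hi))
        if dosages is None:
            dosages = _genotypes_from_p(n_ind, maf, rng)
        vid = f"snp_{chrom}_{pos + 1}"
        emp = float(np.mean(dosages) / 2)
        rec = VariantRecord(chrom, pos, ref, alt, dosages, min(emp, 1 - emp), vid)
        variants.append(rec)
        truth.snp_target_maf[vid] = maf
        if peak_name is not None:
            truth.snp_peak[vid] = peak_name
            if disrupting:
                truth.disrupting_snps[vid] = peak_name
        return rec

    for pk, cat in zip(peaks, categories):
        truth.peak_category[pk.name] = cat
        central = truth.motif_positions[pk.name][0]
        # a high-information motif base: the second consensus position
        disrupt_pos = central + 1
        neutral_pos = pk.summit + int(rng.integers(40, 200))
        while any(abs(neutral_pos - (m + j)) < 2 for m in truth.motif_positions[pk.name]
                  for j in range(len(motif))):
            neutral_pos += 3
        if cat == "single":
            add_snp(disrupt_pos, True, pk.name, True)
            continue
        if cat == "close":
            add_snp(neutral_pos, True, pk.name, False)
            add_snp(neutral_pos + 5, True, pk.name, False)
            continue
        if cat == "highld":
            maf = float(rng.uniform(lo, hi))
            g = _genotypes_from_p(n_ind, maf, rng)
            add_snp(disrupt_pos, True, pk.name, True, dosages=g, maf=maf)
            add_snp(neutral_pos, True, pk.name, False, dosages=g.copy(), maf=maf)
            continue
        # valid and indel peaks both carry a well-formed SNP pair
        add_snp(disrupt_pos, True, pk.name, True)
        add_snp(neutral_pos, True, pk.name, False)
        if cat == "indel":
            ipos = pk.summit - int(rng.integers(100, 240))
            excluded.append(
                ExcludedVariant(chrom, ipos, ipos + 2, "indel", f"indel_{chrom}_{ipos + 1}")
            )
            truth.n_planted_indels += 1

    # intergenic LD blocks between peak loci
    slot = config.genome_length // config.n_peaks
    for b in range(config.n_intergenic_blocks):
        anchor_peak = peaks[int(rng.integers(0, len(peaks) - 1))]
        base = anchor_peak.end + 400
        maf = float(rng.uniform(lo, hi))
        n_snps = config.ld_block_size
        hap = _markov_haplotypes(2 * n_ind, maf, config.ld_rho, n_snps, rng)
        dosages = hap[:, :n_ind].astype(np.float64) + hap[:, n_ind:]
        pos = base
        for j in range(n_snps):
            pos += int(rng.integers(20, 120))
            if pos >= anchor_peak.end + slot - 700:
                break
            add_snp(pos, True, None, False, dosages=dosages[j], maf=maf)

    # oracle allele scores for every peak SNP, and per-peak oracle CAS
    for v in variants:
        if v.vid in truth.snp_peak:
            truth.oracle_allele_scores[v.vid] = oracle_allele_scores(
                v, genome, motif, config.flank
            )
    by_peak: dict[str, list[VariantRecord]] = {}
    for v in variants:
        pk = truth.snp_peak.get(v.vid)
        if pk is not None:
            by_peak.setdefault(pk, []).append(v)
    for pk_name, snps in by_peak.items():
        truth.oracle_cas[pk_name] = oracle_cas(snps, truth.oracle_allele_scores).tolist()

    variants.sort(key=lambda v: v.pos)
    return variants, excluded


# -- stage 3: expression --------------------------------------------------


def simulate_expression(config: SimConfig, variants, peaks, truth: GroundTruth, rng):
    """Counts, TPM and covariates with planted accessibility-driven effects.

    Effect genes' latent log expression is ``beta`` times the standardized
    oracle accessibility score of their causal peak; counts are negative
    binomial (size ``nb_size``) around per-sample scaled means.
    """
    n_ind, n_genes = config.n_individuals, config.n_genes
    samples = [f"S{i:04d}" for i in range(n_ind)]
    cov = rng.standard_normal((config.n_covariates, n_ind))
    covariates = pd.DataFrame(
        cov, index=[f"COV{i+1}" for i in range(config.n_covariates)], columns=samples
    )

    valid_peaks = [p for p in peaks if truth.peak_category[p.name] == "valid"]
    n_effect = int(round(config.effect_fraction * n_genes))
    n_effect = min(n_effect, max(n_genes - config.n_lowexpr_genes, 0))

    gene_ids = [f"GENE_{i:04d}" for i in range(n_genes)]
    genes: list[GeneAnnotation] = []
    latent = np.empty((n_genes, n_ind))
    log_base = np.empty(n_genes)
    L = config.genome_length

    for i, gid in enumerate(gene_ids):
        is_effect = i < n_effect and valid_peaks
        is_low = i >= n_genes - config.n_lowexpr_genes
        loadings = rng.normal(0, config.covariate_loading_sd, config.n_covariates)
        eps = rng.normal(0, config.noise_sd, n_ind)
        signal = 0.0
        if is_effect:
            peak = valid_peaks[i % len(valid_peaks)]
            z = np.asarray(truth.oracle_cas[peak.name])
            sd = z.std()
            z = (z - z.mean()) / sd if sd > 0 else z * 0
            signal = config.beta * z
            truth.effect_genes[gid] = {"peak": peak.name, "beta": config.beta}
            tss = int(np.clip(peak.summit + rng.integers(-200_000, 200_000), 0, L - 1))
        else:
            tss = int(rng.integers(0, L))
        if is_low:
            log_base[i] = np.log(0.05)
            truth.lowexpr_genes.append(gid)
        elif is_effect:
            log_base[i] = rng.normal(np.log(300), 0.5)
        else:
            log_base[i] = rng.normal(np.log(100), 1.5)
        strand = str(rng.choice(["+", "-"]))
        genes.append(GeneAnnotation(gid, config.chrom, tss, strand))
        latent[i] = log_base[i] + signal + loadings @ cov + eps

    # outlier samples: structure replaced by inflated independent noise
    if config.n_outlier_samples > 0:
        out_idx = rng.choice(n_ind, size=config.n_outlier_samples, replace=False)
        for j in out_idx:
            latent[:, j] = log_base + config.outlier_noise_scale * rng.standard_normal(n_genes)
        truth.outlier_samples = [samples[j] for j in sorted(out_idx)]

    lib = np.exp(rng.normal(0, 0.3, n_ind))
    mean = np.exp(latent) * lib
    size = config.nb_size
    counts = rng.negative_binomial(size, size / (size + mean)).astype(np.int64)

    lengths_kb = rng.uniform(0.5, 5.0, n_genes)
    rate = counts / lengths_kb[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=samples)
    return counts_df, tpm_df, covariates, genes, samples


def simulate(config: SimConfig) -> SimData:
    """Run all three stages under one seeded generator."""
    rng = config.rng()
    genome, peaks, truth = simulate_genome_peaks(config, rng)
    variants, excluded = simulate_genotypes(config, genome, peaks, truth, rng)
    counts, tpm, covariates, genes, samples = simulate_expression(
        config, variants, peaks, truth, rng
    )
    return SimData(
        config=config,
        genome=genome,
        peaks=peaks,
        variants=variants,
        excluded=excluded,
        samples=samples,
        counts=counts,
        tpm=tpm,
        covariates=covariates,
        genes=genes,
        truth=truth,
    )


def write_vcf(path, sim: SimData) -> None:
    """Plain-text VCF v4.2 with hard GT calls for all SNPs and indels."""
    recs = []
    for v in sim.variants:
        gts = []
        for d in v.dosages:
            gts.append("./." if np.isnan(d) else {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))])
        recs.append((v.pos, v.vid, v.ref, v.alt, gts))
    rng = np.random.default_rng(sim.config.seed + 1)
    gseq = sim.genome[sim.config.chrom]
    for e in sim.excluded:
        ref = gseq[e.start : e.end].upper()
        alt = ref[0]  # deletion
        g = _genotypes_from_p(len(sim.samples), 0.2, rng)
        gts = [{0: "0/0", 1: "0/1", 2: "1/1"}[int(x)] for x in g]
        recs.append((e.start, e.vid, ref, alt, gts))
    recs.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={sim.config.chrom},length={len(gseq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sim.samples) + "\n")
        for pos, vid, ref, alt, gts in recs:
            fh.write(f"{sim.config.chrom}\t{pos + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
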