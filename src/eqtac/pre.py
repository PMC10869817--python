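"""Potential regulatory elements (PREs) and chromatin accessibility scores.

A PRE is the +/-250 bp window around an accessibility peak summit.  A PRE is
retained only if (i) no indel or insertion overlaps it, (ii) no two of its
SNPs lie closer than 10 bp (their windows would perturb each other's
scores), and (iii) it holds more than one mutually independent SNP at
LD r^2 < 0.3 — otherwise its accessibility score would be collinear with a
single variant or haplotype.

For each retained SNP, the trained sequence model scores the two allele
windows (flank bases on each side of the SNP with ref or alt substituted at
the center), and the per-individual chromatin accessibility score is the
dosage-weighted sum over the PRE's SNPs and alleles:

    CAS = sum_i sum_j S_ij * G_ij

with S_ij the allele-j window score of SNP i and G_ij the individual's
dosage of allele j (G_ref = 2 - g, G_alt = g for alt dosage g in [0, 2]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExcludedVariant, PeakRecord, VariantRecord, fetch_sequence

logger = logging.getLogger("eqtac")

REASON_INDEL = "indel_overlap"
REASON_SPACING = "snp_spacing<10"
REASON_INDEPENDENT = "too_few_independent_snps"


@dataclass
class PRE:
    """A candidate regulatory element and its surviving SNPs."""

    pre_id: str
    chrom: str
    start: int
    end: int
    summit: int
    snps: list[VariantRecord] = field(default_factory=list)
    n_independent: int = 0
    drop_reason: str | None = None

    @property
    def kept(self) -> bool:
        return self.drop_reason is None


def _ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _prune_ld(snps: list[VariantRecord], r2_max: float) -> list[VariantRecord]:
    """Greedy left-to-right pruning: keep a SNP unless it is in LD
    (r^2 >= r2_max, from sample dosage correlation) with an already-kept one."""
    kept: list[VariantRecord] = []
    for snp in snps:
        if all(_ld_r2(snp.dosages, k.dosages) < r2_max for k in kept):
            kept.append(snp)
    return kept


def select_pres(
    peaks: list[PeakRecord],
    variants: list[VariantRecord],
    excluded_variants: list[ExcludedVariant] | None = None,
    ld_r2: float = 0.3,
    min_gap: int = 10,
    radius: int = 250,
) -> list[PRE]:
    """One candidate PRE per peak summit; failing candidates carry a reason.

    Nothing raises: every dropped candidate is returned with its
    ``drop_reason`` so filter tallies can be audited.
    """
    excluded_variants = excluded_variants or []
    by_chrom_snps: dict[str, list[VariantRecord]] = {}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        by_chrom_snps.setdefault(v.chrom, []).append(v)
    by_chrom_excl: dict[str, list[ExcludedVariant]] = {}
    for e in excluded_variants:
        by_chrom_excl.setdefault(e.chrom, []).append(e)

    pres: list[PRE] = []
    for i, pk in enumerate(peaks):
        start, end = pk.summit - radius, pk.summit + radius + 1  # 501 bp closed window
        pre = PRE(f"PRE_{i:05d}_{pk.chrom}_{pk.summit}", pk.chrom, start, end, pk.summit)
        snps = [v for v in by_chrom_snps.get(pk.chrom, []) if start <= v.pos < end]
        pre.snps = snps
        if any(e.start < end and e.end > start for e in by_chrom_excl.get(pk.chrom, [])):
            pre.drop_reason = REASON_INDEL
        elif any(b.pos - a.pos < min_gap for a, b in zip(snps, snps[1:])):
            pre.drop_reason = REASON_SPACING
        else:
            independent = _prune_ld(snps, ld_r2)
            pre.n_independent = len(independent)
            if len(independent) < 2:
                pre.drop_reason = REASON_INDEPENDENT
        pres.append(pre)
    return pres


def pre_table(pres: list[PRE]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pre_id": [p.pre_id for p in pres],
            "chrom": [p.chrom for p in pres],
            "start": [p.start for p in pres],
            "end": [p.end for p in pres],
            "n_snps": [len(p.snps) for p in pres],
            "n_independent": [p.n_independent for p in pres],
            "drop_reason": [p.drop_reason or "" for p in pres],
        }
    ).set_index("pre_id")


class ContigEdgeError(ValueError):
    """SNP window would run off the contig end."""


def allele_windows(
    snp: VariantRecord, genome, flank: int = 9
) -> tuple[str, str]:
    """Reference and alternate sequence windows around a SNP.

    Both windows span [pos - flank, pos + flank], length 2*flank + 1, and are
    identical except at the focal base.  The reference window must match the
    genome exactly; a mismatch means inconsistent inputs and raises.
    """
    start, end = snp.pos - flank, snp.pos + flank + 1
    seq = fetch_sequence(genome, snp.chrom, max(start, 0), end)
    if start < 0 or len(seq) < 2 * flank + 1:
        raise ContigEdgeError(
            f"window [{start}, {end}) for SNP {snp.vid} runs off contig {snp.chrom}"
        )
    seq = seq.upper()
    if seq[flank] != snp.ref.upper():
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos_vcf}: "
            f"genome has {seq[flank]}, VCF says {snp.ref}"
        )
    ref_win = seq
    alt_win = seq[:flank] + snp.alt.upper() + seq[flank + 1 :]
    return ref_win, alt_win


def compute_cas(
    pre: PRE,
    allele_scores: dict[str, tuple[float, float]],
    dosages: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-individual chromatin accessibility score of one PRE.

    ``allele_scores`` maps each SNP id to (S_ref, S_alt).  ``dosages`` may
    override the SNPs' own dosage vectors (rows = variant ids).  Individuals
    with a missing dosage at any contributing SNP get NaN.
    """
    snps = [s for s in pre.snps if s.vid in allele_scores]
    if not snps:
        raise ValueError(f"no scored SNPs for {pre.pre_id}")
    n = len(snps[0].dosages) if dosages is None else dosages.shape[1]
    cas = np.zeros(n)
    for snp in snps:
        s_ref, s_alt = allele_scores[snp.vid]
        g = snp.dosages if dosages is None else dosages.loc[snp.vid].to_numpy()
        cas = cas + s_ref * (2.0 - g) + s_alt * g
    return cas


def cas_matrix(
    pres: list[PRE],
    model,
    genome,
    samples: list[str],
    flank: int = 9,
    missingness_cap: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every retained PRE for every individual.

    Returns (CAS matrix: PREs x samples, allele score table).  SNPs whose
    window leaves the contig are dropped from their PRE with a warning; PREs
    whose CAS is missing for more than ``missingness_cap`` of individuals
    are omitted.
    """
    rows, index = [], []
    score_rows = []
    for pre in pres:
        if not pre.kept:
            continue
        scores: dict[str, tuple[float, float]] = {}
        for snp in pre.snps:
            try:
                ref_win, alt_win = allele_windows(snp, genome, flank)
            except ContigEdgeError as exc:
                logger.warning("%s: %s (SNP dropped)", pre.pre_id, exc)
                continue
            s_ref = model.score(ref_win)
            s_alt = model.score(alt_win)
            scores[snp.vid] = (s_ref, s_alt)
            score_rows.append((pre.pre_id, snp.vid, s_ref, s_alt))
        if not scores:
            logger.warning("%s: no scorable SNPs, PRE omitted", pre.pre_id)
            continue
        cas = compute_cas(pre, scores)
        if np.isnan(cas).mean() > missingness_cap:
            logger.warning("%s: CAS missing for too many individuals, omitted", pre.pre_id)
            continue
        rows.append(cas)
        index.append(pre.pre_id)
    cas_df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(samples))),
                          index=index, columns=samples)
    score_df = pd.DataFrame(score_rows, columns=["pre_id", "snp_id", "s_ref", "s_alt"])
    return cas_df, score_df
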