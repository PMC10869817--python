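"""Readers and writers for the standard formats the pipeline consumes.

Genotypes come from VCF (cyvcf2), sequence from FASTA (pyfaidx or an
in-memory dict of contig strings), peaks from BED3/narrowPeak, and all
matrices travel as TSV with the first column holding gene/PRE/covariate ids
and the header holding sample ids.

All coordinates are 0-based half-open internally; VCF's 1-based positions
are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("eqtac")


@dataclass
class VariantRecord:
    """A biallelic SNP with per-individual alt-allele dosages in [0, 2]."""

    chrom: str
    pos: int  # 0-based position of the SNP base
    ref: str
    alt: str
    dosages: np.ndarray
    maf: float
    vid: str = "."

    @property
    def pos_vcf(self) -> int:
        return self.pos + 1


@dataclass
class ExcludedVariant:
    """A variant set aside by SNP filtering but still needed downstream
    (indels and multiallelics overlap-exclude candidate regulatory elements)."""

    chrom: str
    start: int  # 0-based half-open span on the reference
    end: int
    reason: str
    vid: str = "."


@dataclass
class PeakRecord:
    """An accessibility peak with a single-base summit (0-based half-open)."""

    chrom: str
    start: int
    end: int
    summit: int
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class GeneAnnotation:
    """Gene with its strand-aware TSS (0-based)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass
class GenotypeData:
    samples: list[str]
    variants: list[VariantRecord]
    excluded: list[ExcludedVariant] = field(default_factory=list)
    n_maf_filtered: int = 0
    n_missingness_filtered: int = 0

    def dosage_matrix(self) -> pd.DataFrame:
        """Variants x samples dosage matrix (index = variant ids)."""
        return pd.DataFrame(
            np.vstack([v.dosages for v in self.variants]) if self.variants else
            np.empty((0, len(self.samples))),
            index=[v.vid for v in self.variants],
            columns=self.samples,
        )


def load_genotypes(
    vcf_path, maf_min: float = 0.05, missingness_cap: float = 0.1
) -> GenotypeData:
    """Read biallelic SNPs with MAF >= ``maf_min`` from a VCF.

    Dosages come from the DS format field when present, else from hard GT
    calls.  Indels and multiallelic sites go to the excluded-variant list
    (regulatory-element filters need their footprints); variants with
    missingness above ``missingness_cap`` are dropped and counted.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    excluded: list[ExcludedVariant] = []
    n_maf = n_miss = 0
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}>{','.join(var.ALT)}"
        if len(var.ALT) != 1:
            excluded.append(
                ExcludedVariant(var.CHROM, var.start, var.end, "multiallelic", vid)
            )
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            excluded.append(ExcludedVariant(var.CHROM, var.start, var.end, "indel", vid))
            continue
        dosages = _dosages(var, len(samples))
        missing = np.isnan(dosages)
        if missing.mean() > missingness_cap:
            n_miss += 1
            logger.warning(
                "variant %s dropped: missingness %.2f exceeds cap", vid, missing.mean()
            )
            continue
        mean = np.nanmean(dosages) / 2.0
        maf = min(mean, 1.0 - mean)
        if maf < maf_min:
            n_maf += 1
            continue
        variants.append(
            VariantRecord(var.CHROM, var.start, var.REF, var.ALT[0], dosages, maf, vid)
        )
    return GenotypeData(samples, variants, excluded, n_maf, n_miss)


def _dosages(var, n_samples: int) -> np.ndarray:
    ds = None
    try:
        ds = var.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        d = np.asarray(ds, dtype=np.float64).reshape(n_samples)
        d[(d < 0) | (d > 2)] = np.nan
        return d
    # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt = var.gt_types.astype(np.float64)
    d = np.where(gt == 3, 2.0, gt)
    d[gt == 2] = np.nan
    return d


def load_peaks(bed_path) -> list[PeakRecord]:
    """Read peaks from BED3+ or 10-column narrowPeak.

    narrowPeak's 10th column is the summit offset from ``start`` (-1 meaning
    unknown); for plain BED, and for unknown offsets, the summit defaults to
    the interval midpoint.  Malformed lines and summits outside their
    interval are logged and skipped.
    """
    peaks: list[PeakRecord] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if end <= start:
                    raise ValueError("empty interval")
                name = fields[3] if len(fields) > 3 else f"peak{ln}"
                offset = int(fields[9]) if len(fields) >= 10 else -1
                summit = start + offset if offset >= 0 else start + (end - start) // 2
                peaks.append(PeakRecord(chrom, start, end, summit, name))
            except ValueError as exc:
                logger.warning("%s line %d rejected: %s", bed_path, ln, exc)
    return peaks


def load_genes(path) -> list[GeneAnnotation]:
    """Read gene annotations from TSV (gene_id, chrom, tss, strand) or BED6.

    In BED6 the TSS is the 5' end on the annotated strand: ``start`` for +,
    ``end``-1 for -.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "gene_id" in cols and "tss" in cols:
        df.columns = cols
        return [
            GeneAnnotation(r["gene_id"], r["chrom"], int(r["tss"]), r.get("strand", "+"))
            for _, r in df.iterrows()
        ]
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 6 or line.startswith(("#", "track")):
                continue
            chrom, start, end, gid, _, strand = f[:6]
            tss = int(start) if strand == "+" else int(end) - 1
            genes.append(GeneAnnotation(gid, chrom, tss, strand))
    return genes


# -- genome access --------------------------------------------------------


def open_genome(fasta_path):
    """Open an indexed FASTA, preserving soft-masking case."""
    from pyfaidx import Fasta

    return Fasta(str(fasta_path))


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) of a contig from a pyfaidx Fasta or a dict of strings."""
    start = max(start, 0)
    if isinstance(genome, dict):
        return genome[chrom][start:end]
    seg = genome[chrom][start:end]
    return seg if isinstance(seg, str) else str(seg)


def contig_lengths(genome) -> dict[str, int]:
    if isinstance(genome, dict):
        return {c: len(s) for c, s in genome.items()}
    return {name: len(genome[name]) for name in genome.keys()}


def write_fasta(path, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- matrices -------------------------------------------------------------


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix: first column = row ids, header = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.12g")


def align_samples(*sample_lists: list[str]) -> list[str]:
    """Intersection of sample ids, ordered by the first list (the VCF).

    Raises if the intersection is empty, listing where each offending sample
    set came from.
    """
    base = sample_lists[0]
    common = set(base)
    for sl in sample_lists[1:]:
        common &= set(sl)
    if not common:
        detail = "; ".join(
            f"input {i}: {sorted(sl)[:5]}..." for i, sl in enumerate(sample_lists)
        )
        raise ValueError(f"no samples shared across inputs ({detail})")
    return [s for s in base if s in common]
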