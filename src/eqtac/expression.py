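"""Expression quality control and normalization.

Implements the RNA-seq sample-outlier statistic, gene expression filters,
between-sample TMM scaling and the rank-based inverse normal transform used
to prepare a genes x samples matrix for cis association mapping.

The outlier statistic works on log-transformed TPM: with r_ij the pairwise
sample correlation, each sample gets its average correlation with all
samples, rbar_i = sum_j r_ij / n, and a robust z-like distance

    D_i = (rbar_i - mean(rbar)) / median(|rbar_i - mean(rbar)|),

samples with D_i below a threshold (default -5.0) being flagged as outliers.
The average as written runs over all j including i; excluding the self term
shifts every rbar_i by a constant and rescales the median identically, and
is available via ``exclude_self``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OutlierReport:
    """Per-sample mean correlation, D statistic and outlier flag."""

    table: pd.DataFrame  # columns: r_bar, D, outlier; index: sample ids
    threshold: float

    @property
    def outliers(self) -> list[str]:
        return list(self.table.index[self.table["outlier"]])


def correlation_outlier_stat(
    log_expr: pd.DataFrame,
    threshold: float = -5.0,
    exclude_self: bool = False,
    method: str = "pearson",
) -> OutlierReport:
    """Flag samples whose expression correlates poorly with the cohort.

    Parameters
    ----------
    log_expr
        Genes x samples matrix of log-transformed TPM.
    threshold
        Samples with D below this are flagged (default -5.0).
    exclude_self
        Average each sample's correlations over the other n-1 samples
        instead of all n (the printed formula includes the self term).
    method
        "pearson" (default) or "spearman".
    """
    if log_expr.shape[1] < 3:
        raise ValueError("outlier statistic requires at least 3 samples")
    if method == "pearson":
        corr = np.corrcoef(log_expr.to_numpy(), rowvar=False)
    elif method == "spearman":
        corr = stats.spearmanr(log_expr.to_numpy(), axis=0).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    n = corr.shape[0]
    if exclude_self:
        r_bar = (corr.sum(axis=0) - np.diag(corr)) / (n - 1)
    else:
        r_bar = corr.sum(axis=0) / n
    dev = r_bar - r_bar.mean()
    mad = np.median(np.abs(dev))
    if mad == 0:
        raise ValueError(
            "degenerate correlation structure: all samples equicorrelated (MAD = 0)"
        )
    d = dev / mad
    table = pd.DataFrame(
        {"r_bar": r_bar, "D": d, "outlier": d < threshold}, index=log_expr.columns
    )
    return OutlierReport(table=table, threshold=threshold)


def filter_genes(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tpm_min: float = 0.1,
    count_min: float = 6,
    sample_frac: float = 0.2,
) -> pd.Index:
    """Genes expressed in enough samples: TPM >= 0.1 and raw counts >= 6,
    each in >= 20% of samples (both thresholds inclusive)."""
    if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and TPM matrices must share gene and sample indices")
    n = counts.shape[1]
    ok_tpm = (tpm >= tpm_min).sum(axis=1) >= sample_frac * n
    ok_counts = (counts >= count_min).sum(axis=1) >= sample_frac * n
    return counts.index[ok_tpm & ok_counts]


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series | np.ndarray:
    """Trimmed mean of M-values scale factor per sample (library).

    Follows the published TMM estimator: the reference library is the one
    whose upper-quartile (of count/library-size) is closest to the mean
    upper-quartile; per library, log2 ratios M and average abundances A are
    computed over genes nonzero in both, the extreme 30% of M and 5% of A
    are trimmed (two-sided), and the remaining M are averaged with inverse
    asymptotic-variance weights.  Factors are normalized to geometric mean 1,
    so multiplying each library size by its factor yields effective sizes.
    """
    X = np.asarray(counts, dtype=np.float64)
    if (X < 0).any():
        raise ValueError("negative counts")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample (library size 0)")
    f75 = np.quantile(X / lib, 0.75, axis=0)  # upper quartile of count/libsize, zeros included
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [_tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref], logratio_trim, sum_trim)
         for j in range(X.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(factors, index=counts.columns, name="tmm_factor")
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim) -> float:
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    logR = np.log2((o / n_obs) / (r / n_ref))
    absE = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rR = stats.rankdata(logR)
    rE = stats.rankdata(absE)
    keep = (rR >= loL) & (rR <= hiL) & (rE >= loS) & (rE <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def inverse_normal_transform(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform of one gene's values across samples.

    Maps value with (mid)rank r to Phi^-1((r - offset) / n).  offset=0.5 is
    the default convention; 3/8 gives the Blom variant.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D row of per-sample values")
    if x.size < 3:
        raise ValueError("inverse normal transform requires n >= 3")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    if np.all(x == x[0]):
        raise ValueError("all values equal: rank-degenerate row")
    ranks = stats.rankdata(x)  # average ranks for ties
    return stats.norm.ppf((ranks - offset) / x.size)


def int_matrix(expr: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """Apply the inverse normal transform to every gene row."""
    out = np.vstack([inverse_normal_transform(row, offset) for row in expr.to_numpy()])
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def prepare_expression(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tpm_min: float = 0.1,
    count_min: float = 6,
    sample_frac: float = 0.2,
) -> pd.DataFrame:
    """Filter genes, TMM-scale counts, and inverse-normal-transform each gene.

    Returns the genes x samples matrix fed to association mapping: genes
    passing both expression filters, counts divided by TMM-effective library
    sizes, then each gene row mapped to normal quantiles across samples.
    """
    keep = filter_genes(counts, tpm, tpm_min, count_min, sample_frac)
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    cpm = counts.loc[keep].div(eff_lib, axis=1) * 1e6
    return int_matrix(cpm)
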