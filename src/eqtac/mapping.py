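"""Cis association of accessibility scores with expression (eQTac mapping).

For every PRE-gene pair with the PRE summit within the cis window of the
gene's TSS, expression is regressed on the PRE's chromatin accessibility
score with covariates:

    expression ~ beta1 * CAS + covariates

and the two-sided t-test p-value on beta1 is recorded.  The significance
threshold is calibrated empirically: individual labels of the expression
matrix are permuted (default 100 times, one shared permutation per replicate
across all genes, preserving gene-gene correlation), all pair p-values are
recomputed, and

    FDR(t) = mean_perm frac(p_perm <= t) / frac(p_obs <= t).

The reported p threshold is the largest observed p with FDR(t) <= the target
level.  A nominal per-SNP cis-eQTL scan using the identical regression core
(dosage in place of CAS, BH q-values) labels eQTac regions lacking any
significant single-variant signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation


# -- covariates -----------------------------------------------------------


def hidden_factors(expr: pd.DataFrame, n_factors: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Top principal components of the gene-centered expression matrix.

    Returns (factors x samples DataFrame, fraction of variance explained per
    factor).  These stand in for latent technical/batch structure among the
    mapping covariates.
    """
    n_genes, n_samples = expr.shape
    if n_factors >= min(n_genes, n_samples):
        raise ValueError(
            f"n_factors={n_factors} must be < min(n_genes, n_samples)={min(n_genes, n_samples)}"
        )
    if n_factors == 0:
        return pd.DataFrame(np.empty((0, n_samples)), columns=expr.columns), np.array([])
    X = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var_explained = (s**2 / np.sum(s**2))[:n_factors]
    factors = vt[:n_factors]
    return (
        pd.DataFrame(factors, index=[f"PC{i+1}" for i in range(n_factors)], columns=expr.columns),
        var_explained,
    )


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """[intercept | covariate columns], shape (n, 1 + n_cov)."""
    if covariates is None or covariates.shape[0] == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=np.float64)
    if C.shape[1] != n:
        raise ValueError("covariate matrix must be covariates x individuals")
    X = np.column_stack([np.ones(n), C.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ["intercept"] + list(covariates.index)
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
            f"columns: {names}"
        )
    return X


# -- single-pair regression (the oracle-checkable core) -------------------


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int


def fit_eqtac(
    cas: np.ndarray, expr: np.ndarray, covariates: pd.DataFrame | None = None
) -> AssocResult:
    """OLS of expression on [intercept, CAS, covariates] for one pair.

    beta is the CAS coefficient; p the two-sided t-test with
    n - n_parameters degrees of freedom.  NaNs are removed pairwise
    (complete cases).
    """
    cas = np.asarray(cas, dtype=np.float64)
    expr = np.asarray(expr, dtype=np.float64)
    ok = ~(np.isnan(cas) | np.isnan(expr))
    if covariates is not None and covariates.shape[0] > 0:
        ok &= ~np.isnan(np.asarray(covariates, dtype=np.float64)).any(axis=0)
        cov_ok = covariates.iloc[:, ok] if isinstance(covariates, pd.DataFrame) else None
    else:
        cov_ok = None
    cas, expr = cas[ok], expr[ok]
    n = cas.size
    n_cov = 0 if cov_ok is None else cov_ok.shape[0]
    if n < n_cov + 3:
        raise ValueError(f"too few complete cases (n={n}) for {n_cov} covariates")
    if np.var(cas) == 0:
        raise ValueError("zero-variance accessibility score")
    Z = _design(cov_ok, n)
    X = np.column_stack([Z[:, :1], cas, Z[:, 1:]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: CAS collinear with covariates")
    coef, _, _, _ = np.linalg.lstsq(X, expr, rcond=None)
    resid = expr - X @ coef
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssocResult(beta=beta, se=se, p=max(p, np.finfo(float).tiny), n=n)


# -- vectorized scan ------------------------------------------------------


class _Scanner:
    """Residualize both sides against covariates once, then every pair's
    beta/se/t follows from cross-products (Frisch-Waugh-Lovell)."""

    def __init__(self, covariates: pd.DataFrame | None, n: int):
        X = _design(covariates, n)
        q, _ = np.linalg.qr(X)
        self.q = q
        self.n = n
        self.df = n - X.shape[1] - 1  # + CAS column

    def residualize(self, M: np.ndarray) -> np.ndarray:
        """Rows of M are observations-per-column vectors (rows x n)."""
        return M - (M @ self.q) @ self.q.T

    def pair_stats(self, Yr: np.ndarray, Xr: np.ndarray):
        """t-statistics for all (row of Yr) x (row of Xr) pairs.

        Yr, Xr must already be residualized.  Returns (beta, se, p) arrays of
        shape (Yr rows, Xr rows).
        """
        xss = np.einsum("ij,ij->i", Xr, Xr)
        yss = np.einsum("ij,ij->i", Yr, Yr)
        cross = Yr @ Xr.T
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = cross / xss[None, :]
            rss = yss[:, None] - beta * cross
            sigma2 = rss / self.df
            se = np.sqrt(sigma2 / xss[None, :])
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), self.df)
        return beta, se, np.maximum(p, np.finfo(float).tiny)


# -- pair universe --------------------------------------------------------


def pair_universe(
    pres, genes: list[GeneAnnotation], cis_window: float = 1e6
) -> pd.DataFrame:
    """All PRE-gene pairs with the summit within ``cis_window`` of the TSS.

    Distance is signed relative to transcription: negative upstream of the
    TSS, positive downstream.  The boundary is inclusive.
    """
    rows = []
    by_chrom: dict[str, list] = {}
    for p in pres:
        if getattr(p, "kept", True):
            by_chrom.setdefault(p.chrom, []).append(p)
    for g in genes:
        for p in by_chrom.get(g.chrom, []):
            d = p.summit - g.tss
            if g.strand == "-":
                d = -d
            if abs(d) <= cis_window:
                rows.append((p.pre_id, g.gene_id, d))
    return pd.DataFrame(rows, columns=["pre_id", "gene_id", "distance_to_tss"])


# -- permutation FDR ------------------------------------------------------


@dataclass
class PermutationFDR:
    n_perm: int
    fdr_level: float
    p_threshold: float  # NaN when nothing passes
    observed_p: np.ndarray
    permuted_counts: np.ndarray = field(repr=False)  # E[#perm p <= t] support, see fdr_at
    n_pairs: int = 0

    def fdr_at(self, t: float) -> float:
        obs = np.mean(self.observed_p <= t)
        if obs == 0:
            return np.nan
        perm = (1 + np.sum(self.permuted_counts <= t)) / (self.permuted_counts.size + 1)
        return perm / obs


def _fdr_threshold(p_obs: np.ndarray, p_perm_pool: np.ndarray, fdr: float) -> float:
    """Largest observed p whose permutation FDR estimate is <= ``fdr``.

    The permuted-proportion numerator carries the add-one correction
    standard for permutation tail estimates ((1 + #permuted <= t) /
    (pool size + 1)): a permuted count of zero below a tiny observed p must
    not be read as FDR = 0.
    """
    candidates = np.sort(np.unique(p_obs))
    p_perm_sorted = np.sort(p_perm_pool)
    n_obs = p_obs.size
    n_pool = p_perm_pool.size
    best = np.nan
    obs_sorted = np.sort(p_obs)
    for t in candidates:
        frac_obs = np.searchsorted(obs_sorted, t, side="right") / n_obs
        frac_perm = (1 + np.searchsorted(p_perm_sorted, t, side="right")) / (n_pool + 1)
        if frac_obs > 0 and frac_perm / frac_obs <= fdr:
            best = t if np.isnan(best) else max(best, t)
    return best


def permutation_fdr(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    cas: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
    per_gene: bool = False,
) -> tuple[pd.DataFrame, PermutationFDR]:
    """Observed pair statistics plus a permutation-calibrated p threshold.

    Expression individual labels are permuted ``n_perm`` times — by default
    one shared permutation of individuals per replicate applied to the whole
    matrix (covariates and CAS stay fixed) — and every pair's p-value is
    recomputed to form the null pool.  Returns the per-pair results table
    (beta, se, p, significant) and the threshold object.
    """
    samples = list(expr.columns)
    if list(cas.columns) != samples:
        cas = cas.loc[:, samples]
    if covariates is not None and covariates.shape[0] > 0:
        covariates = covariates.loc[:, samples]
    n = len(samples)
    scanner = _Scanner(covariates, n)

    gene_ids = list(expr.index)
    pre_ids = list(cas.index)
    gi = {g: i for i, g in enumerate(gene_ids)}
    pi = {p: i for i, p in enumerate(pre_ids)}
    pairs = pairs[pairs["gene_id"].isin(gi) & pairs["pre_id"].isin(pi)].reset_index(drop=True)
    rows = pairs["gene_id"].map(gi).to_numpy()
    cols = pairs["pre_id"].map(pi).to_numpy()

    Y = expr.to_numpy(dtype=np.float64)
    C = cas.to_numpy(dtype=np.float64)
    # center+scale CAS per PRE: stabilizes beta reporting, leaves t and p unchanged
    C = C - C.mean(axis=1, keepdims=True)
    sd = C.std(axis=1, ddof=1)
    keep_var = sd > 0
    C[keep_var] = C[keep_var] / sd[keep_var, None]
    var_ok = keep_var[cols]

    Yr = scanner.residualize(Y)
    Xr = scanner.residualize(C)
    beta, se, p = scanner.pair_stats(Yr, Xr)
    p_obs = np.where(var_ok, p[rows, cols], np.nan)

    rng = np.random.default_rng(seed)
    pool = np.empty((n_perm, rows.size))
    for r in range(n_perm):
        if per_gene:
            Yp = np.empty_like(Y)
            for i in range(Y.shape[0]):
                Yp[i] = Y[i, rng.permutation(n)]
        else:
            Yp = Y[:, rng.permutation(n)]
        Ypr = scanner.residualize(Yp)
        _, _, pp = scanner.pair_stats(Ypr, Xr)
        pool[r] = pp[rows, cols]
    # degenerate pairs leave both pools symmetrically
    pool = pool[:, var_ok]
    p_valid = p_obs[var_ok]

    threshold = _fdr_threshold(p_valid, pool.ravel(), fdr)
    significant = np.zeros(rows.size, dtype=bool)
    if not np.isnan(threshold):
        significant = var_ok & (p_obs <= threshold)

    result = pairs.copy()
    result["beta"] = np.where(var_ok, beta[rows, cols], np.nan)
    result["se"] = np.where(var_ok, se[rows, cols], np.nan)
    result["p"] = p_obs
    result["n"] = n
    result["significant"] = significant
    fdr_obj = PermutationFDR(
        n_perm=n_perm,
        fdr_level=fdr,
        p_threshold=threshold,
        observed_p=p_valid,
        permuted_counts=pool.ravel(),
        n_pairs=int(var_ok.sum()),
    )
    return result, fdr_obj


def map_eqtac(
    pres,
    genes: list[GeneAnnotation],
    expr: pd.DataFrame,
    cas: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cis_window: float = 1e6,
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, PermutationFDR]:
    """Full cis scan: build the pair universe, fit every pair, calibrate FDR."""
    pairs = pair_universe(pres, genes, cis_window)
    return permutation_fdr(pairs, expr, cas, covariates, n_perm, fdr, seed)


# -- nominal cis-eQTL companion scan --------------------------------------


def nominal_cis_eqtl(
    dosages: pd.DataFrame,
    variant_pos: dict[str, tuple[str, int]],
    genes: list[GeneAnnotation],
    expr: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cis_window: float = 1e6,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per SNP-gene linear associations in cis with BH q-values.

    Shares the regression core with the accessibility scan (dosage replaces
    CAS).  Used to flag eQTac regions that contain no individually
    significant variant.
    """
    samples = list(expr.columns)
    dosages = dosages.loc[:, samples]
    if covariates is not None and covariates.shape[0] > 0:
        covariates = covariates.loc[:, samples]
    n = len(samples)
    scanner = _Scanner(covariates, n)
    G = dosages.to_numpy(dtype=np.float64)
    Y = expr.to_numpy(dtype=np.float64)
    Yr = scanner.residualize(Y)
    Gr = scanner.residualize(G)
    beta, se, p = scanner.pair_stats(Yr, Gr)

    gi = {g: i for i, g in enumerate(expr.index)}
    vi = {v: i for i, v in enumerate(dosages.index)}
    rows = []
    for g in genes:
        if g.gene_id not in gi:
            continue
        for vid, (chrom, pos) in variant_pos.items():
            if chrom != g.chrom or vid not in vi:
                continue
            d = pos - g.tss
            if g.strand == "-":
                d = -d
            if abs(d) <= cis_window:
                r, c = gi[g.gene_id], vi[vid]
                rows.append((vid, g.gene_id, d, beta[r, c], se[r, c], p[r, c]))
    out = pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "distance_to_tss", "beta", "se", "p"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out
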