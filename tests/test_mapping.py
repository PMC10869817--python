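"""Cis association mapping, permutation FDR and the companion eQTL scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtac.io import GeneAnnotation
from eqtac.mapping import (
    fit_eqtac,
    hidden_factors,
    nominal_cis_eqtl,
    pair_universe,
    permutation_fdr,
)
from eqtac.pre import PRE


def _ols_oracle(y, x, cov=None):
    """Independent normal-equations fit: beta, se, two-sided t-test p."""
    n = len(y)
    cols = [np.ones(n), x] + ([] if cov is None else list(cov))
    X = np.column_stack(cols)
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    t = coef[1] / se
    return coef[1], se, 2 * stats.t.sf(abs(t), df)


class TestPairUniverse:
    def _layout(self, summit, tss, strand="+"):
        pre = PRE("p1", "chr1", summit - 250, summit + 251, summit)
        gene = GeneAnnotation("g1", "chr1", tss, strand)
        return pair_universe([pre], [gene])

    def test_cis_boundary_is_inclusive(self):
        assert len(self._layout(2_000_000, 1_000_000)) == 1
        assert len(self._layout(2_000_001, 1_000_000)) == 0

    def test_distance_sign_is_strand_aware(self):
        # summit 5' of a plus-strand TSS -> upstream, negative
        d = self._layout(900_000, 1_000_000, "+")["distance_to_tss"][0]
        assert d == -100_000
        d = self._layout(900_000, 1_000_000, "-")["distance_to_tss"][0]
        assert d == 100_000

    def test_constructed_geometry_count(self):
        pres = [
            PRE(f"p{i}", "chr1", s - 250, s + 251, s)
            for i, s in enumerate(range(0, 5_000_000, 250_000))
        ]
        genes = [GeneAnnotation("g", "chr1", 2_500_000, "+")]
        pairs = pair_universe(pres, genes)
        analytic = sum(abs(s - 2_500_000) <= 1e6 for s in range(0, 5_000_000, 250_000))
        assert len(pairs) == analytic

    def test_dropped_pres_are_excluded(self):
        bad = PRE("p", "chr1", 0, 501, 250, drop_reason="indel_overlap")
        assert len(pair_universe([bad], [GeneAnnotation("g", "chr1", 0)])) == 0


class TestFitEqtac:
    def test_noiseless_fit_is_exact(self):
        cas = np.arange(20.0)
        res = fit_eqtac(cas, 2.0 * cas)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-100

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = 20
            cas = rng.standard_normal(n)
            y = rng.standard_normal(n)
            cov = pd.DataFrame(rng.standard_normal((2, n)), index=["c1", "c2"])
            res = fit_eqtac(cas, y, cov)
            beta, se, p = _ols_oracle(y, cas, cov.to_numpy())
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_zero_variance_cas_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_eqtac(np.ones(20), rng.standard_normal(20))

    def test_collinear_covariates_named(self, rng):
        n = 20
        c = rng.standard_normal(n)
        cov = pd.DataFrame([c, 2 * c], index=["c1", "c2"])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_eqtac(rng.standard_normal(n), rng.standard_normal(n), cov)

    def test_complete_case_handling(self, rng):
        cas = rng.standard_normal(30)
        y = 1.5 * cas + rng.standard_normal(30) * 0.1
        cas_nan = cas.copy()
        cas_nan[[3, 7]] = np.nan
        res = fit_eqtac(cas_nan, y)
        keep = np.delete(np.arange(30), [3, 7])
        ref = fit_eqtac(cas[keep], y[keep])
        assert res.n == 28 and res.beta == pytest.approx(ref.beta, abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(1000):
            ps.append(fit_eqtac(rng.standard_normal(30), rng.standard_normal(30)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def _null_frame(rng, n_genes, n_pre, n):
    expr = pd.DataFrame(
        rng.standard_normal((n_genes, n)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n)],
    )
    cas = pd.DataFrame(
        rng.standard_normal((n_pre, n)),
        index=[f"p{i}" for i in range(n_pre)],
        columns=expr.columns,
    )
    pairs = pd.DataFrame(
        [(p, g, 0) for p in cas.index for g in expr.index],
        columns=["pre_id", "gene_id", "distance_to_tss"],
    )
    return expr, cas, pairs


class TestPermutationFDR:
    def _planted(self, seed, n=200, n_genes=100, n_pre=10, n_effects=50, beta=1.0):
        rng = np.random.default_rng(seed)
        expr, cas, pairs = _null_frame(rng, n_genes, n_pre, n)
        planted = []
        for i in range(n_effects):
            g, p = f"g{i}", f"p{i % n_pre}"
            expr.loc[g] = beta * cas.loc[p] + rng.standard_normal(n)
            planted.append((p, g))
        return expr, cas, pairs, planted

    def test_recovers_planted_strong_effects(self):
        """>= 80% of pairs with beta=1, sd=1, n=200 planted among 1000 pairs
        are flagged at permutation FDR 0.05."""
        expr, cas, pairs, planted = self._planted(seed=0)
        res, fdr = permutation_fdr(pairs, expr, cas, n_perm=100, seed=1)
        flagged = set(zip(res[res.significant].pre_id, res[res.significant].gene_id))
        recovered = sum(pg in flagged for pg in planted)
        assert recovered >= 0.8 * len(planted)

    def test_flagged_set_stable_under_more_permutations(self):
        expr, cas, pairs, _ = self._planted(seed=3)
        r1, _ = permutation_fdr(pairs, expr, cas, n_perm=100, seed=5)
        r2, _ = permutation_fdr(pairs, expr, cas, n_perm=200, seed=5)
        s1 = set(zip(r1[r1.significant].pre_id, r1[r1.significant].gene_id))
        s2 = set(zip(r2[r2.significant].pre_id, r2[r2.significant].gene_id))
        jaccard = len(s1 & s2) / max(len(s1 | s2), 1)
        assert jaccard >= 0.9

    def test_null_data_rarely_flags(self):
        rng = np.random.default_rng(10)
        expr, cas, pairs = _null_frame(rng, 50, 10, 100)
        res, fdr = permutation_fdr(pairs, expr, cas, n_perm=100, seed=11)
        assert res.significant.sum() <= 5  # no planted signal to find

    def test_per_gene_permutation_mode(self):
        expr, cas, pairs, planted = self._planted(seed=7, n_genes=30, n_effects=10)
        res, _ = permutation_fdr(pairs, expr, cas, n_perm=50, seed=7, per_gene=True)
        flagged = set(zip(res[res.significant].pre_id, res[res.significant].gene_id))
        assert sum(pg in flagged for pg in planted) >= 0.8 * len(planted)

    def test_degenerate_cas_row_excluded_symmetrically(self):
        rng = np.random.default_rng(9)
        expr, cas, pairs = _null_frame(rng, 20, 4, 50)
        cas.loc["p0"] = 1.0  # zero variance
        res, fdr = permutation_fdr(pairs, expr, cas, n_perm=20, seed=9)
        assert res.loc[res.pre_id == "p0", "p"].isna().all()
        assert fdr.n_pairs == 3 * 20


class TestNominalEqtl:
    def test_matches_fit_eqtac_with_dosage_column(self, rng):
        n = 60
        dosage = rng.integers(0, 3, n).astype(float)
        expr = pd.DataFrame(
            [1.2 * dosage + rng.standard_normal(n)],
            index=["g1"], columns=[f"s{i}" for i in range(n)],
        )
        dos = pd.DataFrame([dosage], index=["v1"], columns=expr.columns)
        cov = pd.DataFrame(rng.standard_normal((2, n)),
                           index=["c1", "c2"], columns=expr.columns)
        out = nominal_cis_eqtl(dos, {"v1": ("chr1", 500)},
                               [GeneAnnotation("g1", "chr1", 600)], expr, cov)
        # the scan standardizes nothing: same model as the per-pair fit
        ref = fit_eqtac(dosage, expr.loc["g1"].to_numpy(), cov)
        assert out.loc[0, "beta"] == pytest.approx(ref.beta, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(ref.p, rel=1e-8)

    def test_perfect_dosage_effect(self, rng):
        n = 30
        dosage = rng.integers(0, 3, n).astype(float)
        expr = pd.DataFrame([dosage], index=["g1"], columns=[f"s{i}" for i in range(n)])
        dos = pd.DataFrame([dosage], index=["v1"], columns=expr.columns)
        out = nominal_cis_eqtl(dos, {"v1": ("chr1", 10)},
                               [GeneAnnotation("g1", "chr1", 20)], expr)
        assert out.loc[0, "beta"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc[0, "p"] < 1e-50

    def test_bh_null_calibration(self):
        rng = np.random.default_rng(21)
        n, n_genes, n_snp = 100, 40, 10
        expr = pd.DataFrame(rng.standard_normal((n_genes, n)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n)])
        dos = pd.DataFrame(rng.integers(0, 3, (n_snp, n)).astype(float),
                           index=[f"v{i}" for i in range(n_snp)], columns=expr.columns)
        vpos = {f"v{i}": ("chr1", 100 + i) for i in range(n_snp)}
        genes = [GeneAnnotation(f"g{i}", "chr1", 200) for i in range(n_genes)]
        out = nominal_cis_eqtl(dos, vpos, genes, expr)
        assert out["significant"].mean() <= 0.05


class TestHiddenFactors:
    def test_recovers_planted_batch_factor(self, rng):
        n, n_genes = 80, 120
        batch = rng.standard_normal(n)
        loadings = rng.standard_normal(n_genes)
        expr = pd.DataFrame(np.outer(loadings, batch) + 0.05 * rng.standard_normal((n_genes, n)),
                            columns=[f"s{i}" for i in range(n)])
        factors, var = hidden_factors(expr, 2)
        r = np.corrcoef(factors.iloc[0], batch)[0, 1]
        assert abs(r) > 0.99 and var[0] > 0.9

    def test_factors_are_orthonormal(self, rng):
        expr = pd.DataFrame(rng.standard_normal((50, 40)))
        factors, _ = hidden_factors(expr, 5)
        gram = factors.to_numpy() @ factors.to_numpy().T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_zero_factors_is_empty_block(self, rng):
        factors, var = hidden_factors(pd.DataFrame(rng.standard_normal((10, 8))), 0)
        assert factors.shape == (0, 8) and var.size == 0

    def test_too_many_factors_rejected(self, rng):
        with pytest.raises(ValueError):
            hidden_factors(pd.DataFrame(rng.standard_normal((10, 8))), 8)


def test_beta_estimates_are_unbiased():
    """Planted beta=0.5, n=200, sd=1: mean estimation error < 0.05 over
    replicates (CAS standardized per PRE, so beta is on the CAS-sd scale)."""
    errors = []
    for seed in range(40):
        rng = np.random.default_rng(seed)
        n = 200
        cas_row = rng.standard_normal(n)
        z = (cas_row - cas_row.mean()) / cas_row.std(ddof=1)
        y = 0.5 * z + rng.standard_normal(n)
        expr = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(n)])
        cas = pd.DataFrame([cas_row], index=["p"], columns=expr.columns)
        pairs = pd.DataFrame([("p", "g", 0)],
                             columns=["pre_id", "gene_id", "distance_to_tss"])
        res, _ = permutation_fdr(pairs, expr, cas, n_perm=2, seed=seed)
        errors.append(res.loc[0, "beta"] - 0.5)
    assert abs(np.mean(errors)) < 0.05
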