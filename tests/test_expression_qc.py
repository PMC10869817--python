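"""Expression QC: outlier statistic, gene filters, TMM scaling, INT."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtac.expression import (
    correlation_outlier_stat,
    filter_genes,
    int_matrix,
    inverse_normal_transform,
    prepare_expression,
    tmm_factors,
)


def _log_expr(rng, n_genes=200, n_samples=10, outlier=None):
    base = rng.normal(5, 2, n_genes)
    X = base[:, None] + rng.normal(0, 0.5, (n_genes, n_samples))
    if outlier is not None:
        X[:, outlier] = rng.normal(5, 2, n_genes)  # no shared structure
    return pd.DataFrame(X, columns=[f"s{i}" for i in range(n_samples)])


class TestOutlierStat:
    def test_matches_direct_formula_oracle(self, rng):
        """r_bar and D recomputed naively from the correlation matrix agree
        to 1e-12, and the planted outlier attains the minimum D."""
        X = _log_expr(rng, outlier=3)
        rep = correlation_outlier_stat(X)
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        n = corr.shape[0]
        r_bar = np.array([sum(corr[i, j] for j in range(n)) / n for i in range(n)])
        d = (r_bar - r_bar.mean()) / np.median(np.abs(r_bar - r_bar.mean()))
        np.testing.assert_allclose(rep.table["r_bar"].to_numpy(), r_bar, atol=1e-12)
        np.testing.assert_allclose(rep.table["D"].to_numpy(), d, atol=1e-12)
        assert rep.table["D"].idxmin() == "s3"

    def test_identical_samples_are_degenerate(self, rng):
        col = rng.normal(size=50)
        X = pd.DataFrame(np.column_stack([col, col, col]))
        with pytest.raises(ValueError, match="degenerate"):
            correlation_outlier_stat(X)

    def test_sample_order_invariance(self, rng):
        X = _log_expr(rng, outlier=2)
        rep = correlation_outlier_stat(X)
        perm = X.iloc[:, rng.permutation(X.shape[1])]
        rep2 = correlation_outlier_stat(perm)
        pd.testing.assert_series_equal(
            rep.table["D"].sort_index(), rep2.table["D"].sort_index()
        )

    def test_self_term_cancels_in_d(self, rng):
        # including or excluding j=i shifts r_bar by a constant and rescales
        # the MAD identically, so D is unchanged
        X = _log_expr(rng, outlier=1)
        d_incl = correlation_outlier_stat(X, exclude_self=False).table["D"]
        d_excl = correlation_outlier_stat(X, exclude_self=True).table["D"]
        np.testing.assert_allclose(d_incl, d_excl, atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        X = _log_expr(rng, outlier=0)
        d0 = correlation_outlier_stat(X).table["D"]
        d1 = correlation_outlier_stat(3.7 * X + 11.0).table["D"]
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_planted_cohort_outliers_flagged(self):
        from eqtac.simulate import SimConfig, simulate

        sim = simulate(
            SimConfig(seed=5, n_individuals=50, n_genes=300, n_peaks=10,
                      genome_length=20_000, n_intergenic_blocks=0,
                      n_lowexpr_genes=0, n_outlier_samples=2)
        )
        log_tpm = np.log2(sim.tpm + 1.0)
        rep = correlation_outlier_stat(log_tpm)
        assert set(rep.outliers) == set(sim.truth.outlier_samples)


class TestGeneFilters:
    def _matrices(self, tpm_vals, count_vals):
        cols = [f"s{i}" for i in range(len(tpm_vals))]
        return (
            pd.DataFrame([count_vals], index=["g"], columns=cols),
            pd.DataFrame([tpm_vals], index=["g"], columns=cols),
        )

    def test_boundary_thresholds_are_inclusive(self):
        # TPM exactly 0.1 in exactly 20% of 10 samples, counts >= 6 in 2/10
        counts, tpm = self._matrices(
            [0.1, 0.1] + [0.0] * 8, [6, 7] + [0] * 8
        )
        assert list(filter_genes(counts, tpm)) == ["g"]

    def test_low_tpm_gene_dropped(self):
        counts, tpm = self._matrices([0.09] * 10, [100] * 10)
        assert len(filter_genes(counts, tpm)) == 0

    def test_mismatched_indices_rejected(self):
        counts, tpm = self._matrices([1] * 4, [10] * 4)
        with pytest.raises(ValueError):
            filter_genes(counts, tpm.rename(columns={"s0": "x"}))

    def test_constructed_matrix_bookkeeping(self, rng):
        """500 genes of which 120 are built to fail exactly one criterion."""
        n = 10
        counts = pd.DataFrame(
            rng.integers(50, 500, (500, n)), index=[f"g{i}" for i in range(500)]
        )
        tpm = pd.DataFrame(
            rng.uniform(1, 50, (500, n)), index=counts.index, columns=counts.columns
        )
        fail = rng.choice(500, 120, replace=False)
        half = fail[:60]
        tpm.iloc[half] = 0.05  # fails the TPM criterion only
        counts.iloc[fail[60:]] = 2  # fails the count criterion only
        kept = filter_genes(counts, tpm)
        assert len(kept) == 380
        assert not set(counts.index[fail]) & set(kept)


class TestTMM:
    def test_identical_libraries(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(tmm_factors(counts), [1.0, 1.0], atol=1e-12)

    def test_depth_insensitivity(self, rng):
        a = rng.integers(1, 1000, 200)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f["a"], f["b"], atol=1e-12)

    def test_hand_computed_weighted_trimmed_mean(self):
        """Two libraries, five genes, one extreme DE gene whose M-value falls
        outside the 30% two-sided trim: the surviving genes' weighted mean of
        M reproduces the factor (direct-sum oracle)."""
        obs = np.array([100.0, 200.0, 300.0, 400.0, 10_000.0])
        ref = np.array([100.0, 200.0, 300.0, 400.0, 100.0])
        counts = pd.DataFrame({"obs": obs, "ref": ref})
        n_o, n_r = obs.sum(), ref.sum()
        logR = np.log2((obs / n_o) / (ref / n_r))
        absE = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
        n = 5
        loL, hiL = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        loS, hiS = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rR, rE = stats.rankdata(logR), stats.rankdata(absE)
        keep = (rR >= loL) & (rR <= hiL) & (rE >= loS) & (rE <= hiS)
        f_obs = 2 ** (np.sum(logR[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected = np.array([f_obs, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(tmm_factors(counts), expected, atol=1e-12)

    def test_matches_edger_reference(self, rng, tmp_path):
        """Cross-check against the Bioconductor TMM implementation."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(80, 4)),
            columns=list("abcd"),
        )
        counts.iloc[:10, 0] *= 5  # some genuinely DE genes
        csv = tmp_path / "c.csv"
        counts.to_csv(csv, index=False)
        script = (
            f"x <- as.matrix(read.csv('{csv}'));"
            "suppressMessages(library(edgeR));"
            "cat(sprintf('%.12f', calcNormFactors(x, method='TMM')), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(counts), reference, atol=1e-8)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


class TestINT:
    def test_three_sample_closed_form(self):
        out = inverse_normal_transform([3.0, 1.0, 2.0])
        expected = stats.norm.ppf([5 / 6, 1 / 6, 1 / 2])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[2] == 0.0

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_array_equal(
            inverse_normal_transform(x), inverse_normal_transform(5 * x - 2)
        )

    def test_ties_share_midrank_quantile(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        # tied entries get the average rank 2.5 -> Phi^-1((2.5-0.5)/4) = 0
        assert out[1] == out[2] == pytest.approx(stats.norm.ppf(0.5), abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 1.0, 1.0])

    def test_monotone_in_ranks(self, rng):
        x = rng.normal(size=50)
        out = inverse_normal_transform(x)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    def test_output_is_standard_normal(self, rng):
        x = rng.exponential(size=500)
        out = inverse_normal_transform(x)
        assert stats.kstest(out, "norm").pvalue > 0.01
        assert abs(out.mean()) < 1e-6

    def test_int_is_idempotent(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 40)))
        once = int_matrix(expr)
        twice = int_matrix(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)


def test_prepare_expression_pipeline(small_sim):
    expr = prepare_expression(small_sim.counts, small_sim.tpm)
    # low-expression genes built to fail the filters are gone
    assert not set(small_sim.truth.lowexpr_genes) & set(expr.index)
    # rows are normal quantiles; ties (zero counts) can shift the mean a little
    assert np.abs(expr.mean(axis=1)).max() < 0.5
    tie_free = expr.index[
        [small_sim.counts.loc[g].nunique() == small_sim.counts.shape[1] for g in expr.index]
    ]
    assert np.abs(expr.loc[tie_free].mean(axis=1)).max() < 1e-9
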