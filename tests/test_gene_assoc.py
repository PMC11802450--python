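"""Gene windows, probit z, weighted chi-square p-values, gene-gene LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellgwas import (
    GeneModel,
    annotate_snps_to_genes,
    gene_gene_correlation,
    gene_statistic,
    ld_eigenvalues,
    mixture_pvalue,
    run_gene_analysis,
    snp_z_from_p,
)
from conftest import exact_correlation_sample


def snp_table(positions, chrom="1"):
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        }
    )


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


class TestAnnotation:
    def test_plus_strand_window_boundaries_inclusive(self):
        genes = gene_table([("g", "1", 100_000, 110_000, "+")])
        snps = snp_table([64_999, 65_000, 120_000, 120_001])
        models = annotate_snps_to_genes(snps, genes)
        assert models[0].snp_ids == ["rs1", "rs2"]  # 65,000 .. 120,000

    def test_minus_strand_window_is_mirrored(self):
        genes = gene_table([("g", "1", 100_000, 110_000, "-")])
        snps = snp_table([89_999, 90_000, 145_000, 145_001])
        models = annotate_snps_to_genes(snps, genes)
        assert models[0].snp_ids == ["rs1", "rs2"]  # 90,000 .. 145,000

    def test_snp_shared_by_overlapping_genes(self):
        genes = gene_table(
            [("a", "1", 100_000, 110_000, "+"), ("b", "1", 105_000, 115_000, "+")]
        )
        models = annotate_snps_to_genes(snp_table([107_000]), genes)
        assert [m.gene for m in models] == ["a", "b"]
        assert all(m.snp_ids == ["rs0"] for m in models)

    def test_chromosome_naming_mismatch_raises(self):
        genes = gene_table([("g", "chr1", 100, 200, "+")])
        with pytest.raises(ValueError, match="chr1"):
            annotate_snps_to_genes(snp_table([150], chrom="1"), genes)

    def test_snpless_gene_dropped_with_warning(self):
        genes = gene_table(
            [("g", "1", 100_000, 110_000, "+"), ("far", "1", 900_000, 910_000, "+")]
        )
        with pytest.warns(UserWarning, match="no SNPs"):
            models = annotate_snps_to_genes(snp_table([100_500]), genes)
        assert [m.gene for m in models] == ["g"]


class TestProbit:
    @pytest.mark.parametrize(
        "p, z", [(0.5, 0.0), (0.05, 1.6449), (1.0, -8.2)]
    )
    def test_quantiles(self, p, z):
        if p == 1.0:
            assert np.isfinite(snp_z_from_p(p)) and snp_z_from_p(p) < z
        else:
            assert snp_z_from_p(p) == pytest.approx(z, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            snp_z_from_p(p)


class TestGeneStatistic:
    def test_values_and_monotonicity(self):
        assert gene_statistic([0.0, 0.0, 0.0]) == 0.0
        assert gene_statistic([1.0, 2.0]) == 5.0
        assert gene_statistic([1.0, 2.5]) > gene_statistic([1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_statistic([])


class TestLdEigenvalues:
    def test_independent_snps_give_unit_spectrum(self, rng):
        X = exact_correlation_sample(np.eye(6), 400, rng)
        lam, n_pruned, trace = ld_eigenvalues(X)
        assert np.allclose(lam, 1.0, atol=1e-8)
        assert trace == pytest.approx(6.0, abs=1e-6)
        assert n_pruned == 0

    def test_perfectly_correlated_pair(self, rng):
        x = rng.standard_normal(300)
        lam, n_pruned, trace = ld_eigenvalues(np.column_stack([x, x]))
        assert lam[0] == pytest.approx(2.0, abs=1e-9)
        assert n_pruned == 1  # the zero eigenvalue is pruned
        assert trace == pytest.approx(2.0, abs=1e-6)

    def test_equicorrelation_closed_form(self, rng):
        R = np.full((5, 5), 0.8)
        np.fill_diagonal(R, 1.0)
        X = exact_correlation_sample(R, 500, rng)
        lam, _, trace = ld_eigenvalues(X)
        assert lam[0] == pytest.approx(1 + 4 * 0.8, abs=1e-6)
        assert np.allclose(lam[1:], 0.2, atol=1e-6)
        assert trace == pytest.approx(5.0, abs=1e-6)

    def test_zero_variance_snp_removed(self, rng):
        X = np.column_stack([rng.standard_normal(100), np.ones(100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            lam, _, _ = ld_eigenvalues(X)
        assert lam.size == 1


class TestMixturePvalue:
    def test_boundary_and_closed_forms(self):
        assert mixture_pvalue(0.0, [1.0, 2.0]) == 1.0
        assert mixture_pvalue(3.0, [1.0, 1.0]) == pytest.approx(np.exp(-1.5), abs=1e-9)
        assert mixture_pvalue(2.7055, [1.0]) == pytest.approx(0.1000, abs=1e-4)

    def test_equal_weights_match_exact_chi2(self):
        for T in [0.5, 2.0, 10.0, 35.0]:
            p = mixture_pvalue(T, [0.7, 0.7, 0.7])
            assert p == pytest.approx(stats.chi2.sf(T / 0.7, 3), abs=1e-9)

    def test_unequal_weights_match_monte_carlo(self, rng):
        lam = np.array([2.0, 1.0, 0.5])
        draws = (lam * rng.chisquare(1, size=(200_000, 3))).sum(axis=1)
        for T in [2.0, 5.0, 9.0]:
            mc = (draws > T).mean()
            assert mixture_pvalue(T, lam) == pytest.approx(mc, abs=0.005)

    def test_far_tail_continuity_across_methods(self):
        # Imhof and the saddlepoint fallback must agree where they hand over
        lam = [1.7, 1.1, 0.6, 0.3]
        p_grid = [mixture_pvalue(T, lam) for T in np.linspace(30, 70, 30)]
        assert all(a > b for a, b in zip(p_grid, p_grid[1:]))  # monotone in T
        assert p_grid[-1] > 0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            mixture_pvalue(-1.0, [1.0])

    @given(st.floats(min_value=0.0, max_value=80.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_result_is_probability(self, T):
        assert 0.0 < mixture_pvalue(T, [1.3, 0.9, 0.4]) <= 1.0


def make_model(gene, indices, chrom="1", w_start=1, w_end=100):
    return GeneModel(gene, chrom, w_start, w_end, np.asarray(indices))


class TestGeneGeneCorrelation:
    def test_disjoint_chromosomes_uncorrelated(self, rng):
        panel = rng.standard_normal((200, 4))
        models = [
            make_model("a", [0, 1], chrom="1"),
            make_model("b", [2, 3], chrom="2"),
        ]
        corr = gene_gene_correlation(models, panel)
        assert corr.matrix[0, 1] == 0.0

    def test_duplicated_gene_fully_correlated(self, rng):
        R = np.full((4, 4), 0.6)
        np.fill_diagonal(R, 1.0)
        panel = exact_correlation_sample(R, 300, rng)
        models = [make_model("a", [0, 1, 2, 3]), make_model("b", [0, 1, 2, 3], w_start=2)]
        corr = gene_gene_correlation(models, panel)
        assert corr.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_shared_block_matches_monte_carlo(self, rng):
        """Genes sharing half their SNPs inside one LD block: the analytic
        cross-LD correlation matches corr(T_g, T_h) over simulated nulls."""
        k = 6
        R = np.full((k, k), 0.9)
        np.fill_diagonal(R, 1.0)
        panel = exact_correlation_sample(R, 500, rng)
        g = make_model("g", [0, 1, 2, 3])
        h = make_model("h", [2, 3, 4, 5], w_start=3)
        corr = gene_gene_correlation([g, h], panel)

        L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        z = rng.standard_normal((10_000, k)) @ L.T
        Tg = (z[:, :4] ** 2).sum(axis=1)
        Th = (z[:, 2:] ** 2).sum(axis=1)
        mc = np.corrcoef(Tg, Th)[0, 1]
        assert corr.matrix[0, 1] == pytest.approx(mc, abs=0.05)

    def test_matrix_is_positive_semidefinite(self, planted_run):
        w = np.linalg.eigvalsh(planted_run["corr"].matrix)
        assert w.min() > -1e-8


class TestRunGeneAnalysis:
    def _inputs(self, pvals, rng):
        n = len(pvals)
        snps = snp_table([100_000 + 1_000 * i for i in range(n)])
        snps["mac"] = 50
        genes = gene_table([("g", "1", 90_000, 90_000 + 1_000 * n + 20_000, "+")])
        panel = rng.binomial(1, 0.3, size=(200, n)).astype(float)
        gwas = pd.DataFrame(
            {"SNP": snps["snp"], "CHR": "1", "BP": snps["pos"], "P": pvals, "N": 10_000}
        )
        return gwas, genes, panel, snps

    def test_single_snp_gene_composes_probit_and_chi2(self, rng):
        gwas, genes, panel, snps = self._inputs([0.05], rng)
        gs, _, _ = run_gene_analysis(gwas, genes, panel, snps)
        row = gs.iloc[0]
        assert row["STAT"] == pytest.approx(2.7055, abs=1e-3)
        assert row["P"] == pytest.approx(0.10, abs=1e-3)

    def test_null_snps_give_unit_pvalue(self, rng):
        gwas, genes, panel, snps = self._inputs([0.5, 0.5, 0.5], rng)
        gs, _, _ = run_gene_analysis(gwas, genes, panel, snps)
        assert gs.iloc[0]["STAT"] == 0.0
        assert gs.iloc[0]["P"] == 1.0

    def test_unmapped_gwas_snp_rejected(self, rng):
        gwas, genes, panel, snps = self._inputs([0.5], rng)
        bad = pd.concat(
            [gwas, pd.DataFrame([{"SNP": "rs_nowhere", "CHR": "1", "BP": 5, "P": 0.1, "N": 1}])]
        )
        with pytest.raises(ValueError, match="missing from the panel"):
            run_gene_analysis(bad, genes, panel, snps)

    def test_gene_pvalues_uniform_under_null(self, rng):
        """2,000 single-SNP genes with uniform GWAS p-values give uniform
        gene-level p-values."""
        n = 2_000
        period = 60_000
        pos = [40_000 + period * i for i in range(n)]
        snps = snp_table(pos)
        snps["mac"] = 50
        genes = gene_table(
            [(f"g{i}", "1", pos[i] - 1_000, pos[i] + 1_000, "+") for i in range(n)]
        )
        panel = rng.binomial(1, 0.3, size=(60, n)).astype(float)
        gwas = pd.DataFrame(
            {"SNP": snps["snp"], "CHR": "1", "BP": snps["pos"],
             "P": rng.uniform(size=n), "N": 10_000}
        )
        gs, _, _ = run_gene_analysis(gwas, genes, panel, snps)
        assert len(gs) == n
        assert stats.kstest(gs["P"], "uniform").pvalue > 0.01

    def test_trace_conservation(self, planted_run):
        for m in planted_run["models"][:50]:
            assert m.trace == pytest.approx(m.n_snps, abs=1e-6)
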